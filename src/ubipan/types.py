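"""Shared domain types for the pan-cancer E3/DUB multi-omics pipeline.

All tabular data is carried in pandas containers; the dataclasses here add
the study-design semantics (tumor/normal conditions, sample pairing, enzyme
catalogs, interaction networks, signed pathway topologies) and validate the
invariants the downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("tumor", "normal")


class UbipanError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class AbundanceMatrix:
    """A features x samples abundance table with its sample design.

    ``values`` holds log-ratio abundances (or normalized counts) with NaN
    for missing cells.  ``design`` is indexed by sample_id and carries
    ``cohort``, ``condition`` ("tumor"/"normal") and an optional ``pair_id``
    linking a tumor sample to its normal adjacent tissue from the same
    subject.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise UbipanError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise UbipanError(f"duplicate sample ids: {dups[:5]}")
        missing_design = [s for s in self.values.columns if s not in self.design.index]
        if missing_design:
            raise UbipanError(
                f"samples absent from design: {missing_design[:5]}"
            )
        self.design = self.design.loc[list(self.values.columns)]
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise UbipanError(f"unknown conditions: {sorted(bad)}")
        if "pair_id" in self.design.columns:
            paired = self.design.dropna(subset=["pair_id"])
            counts = paired.groupby(["pair_id", "condition"]).size()
            if (counts > 1).any():
                raise UbipanError("a pair_id maps to more than one sample per condition")
        else:
            self.design = self.design.assign(pair_id=pd.Series(dtype=object))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])

    @property
    def is_paired(self) -> bool:
        """True when at least 3 tumor/normal pairs are present."""
        return len(self.complete_pairs()) >= 3

    def complete_pairs(self) -> list[tuple[str, str]]:
        """(tumor_sample, normal_sample) tuples for every complete pair."""
        paired = self.design.dropna(subset=["pair_id"])
        out = []
        for _, grp in paired.groupby("pair_id", sort=True):
            by_cond = grp.reset_index().set_index("condition")
            if {"tumor", "normal"} <= set(by_cond.index):
                out.append((by_cond.loc["tumor"].iloc[0], by_cond.loc["normal"].iloc[0]))
        return out

    def subset_features(self, features: list[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[features], self.design.copy())

    def subset_samples(self, samples: list[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values[samples], self.design.loc[samples].copy())

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class EnzymeCatalog:
    """Catalogs of E3 ubiquitin ligases and deubiquitinases, symbol-keyed."""

    e3: set[str]
    dub: set[str]
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.e3 and not self.dub:
            raise UbipanError("empty enzyme catalog")
        overlap = self.e3 & self.dub
        if overlap and not self.allow_overlap:
            raise UbipanError(
                f"E3/DUB catalogs intersect ({sorted(overlap)[:5]}); "
                "pass allow_overlap=True if intended"
            )


@dataclass
class ESINetwork:
    """Directed, experimentally supported E3 -> substrate interactions."""

    edges: set[tuple[str, str, str]]  # (e3, substrate, source)
    allow_self: bool = False

    def __post_init__(self) -> None:
        pairs = [(e, s) for e, s, _ in self.edges]
        if len(pairs) != len(set(pairs)):
            raise UbipanError("duplicate (e3, substrate) edges")
        if not self.allow_self:
            selfs = [p for p in pairs if p[0] == p[1]]
            if selfs:
                raise UbipanError(f"self-edges not allowed: {selfs[:5]}")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted((e, s) for e, s, _ in self.edges)

    def substrates_of(self, e3: str) -> set[str]:
        return {s for e, s, _ in self.edges if e == e3}

    @property
    def e3s(self) -> set[str]:
        return {e for e, _, _ in self.edges}

    @property
    def substrates(self) -> set[str]:
        return {s for _, s, _ in self.edges}


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) for over-representation analysis."""

    sets: dict[str, tuple[str, frozenset[str]]]  # set_id -> (name, members)

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise UbipanError(f"gene set {set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


@dataclass
class PathwayGraph:
    """A signed signaling topology: edges carry +1 (activation) / -1 (inhibition)."""

    pathway_id: str
    nodes: list[str]
    edges: list[tuple[str, str, int, str]]  # (source, target, sign, relation)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise UbipanError(f"pathway {self.pathway_id}: duplicate nodes")
        for src, tgt, sign, _ in self.edges:
            if sign not in (1, -1):
                raise UbipanError(
                    f"pathway {self.pathway_id}: edge sign must be +1/-1, got {sign!r}"
                )
            if src not in node_set or tgt not in node_set:
                raise UbipanError(
                    f"pathway {self.pathway_id}: edge endpoint not in node list "
                    f"({src!r}->{tgt!r})"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class SurvivalTable:
    """Per-sample time-to-event records with a continuous marker covariate."""

    records: pd.DataFrame  # columns: sample_id, time, event, marker

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event", "marker"}
        missing = required - set(self.records.columns)
        if missing:
            raise UbipanError(f"survival table missing columns: {sorted(missing)}")
        if (self.records["time"] < 0).any():
            raise UbipanError("negative survival times")
        if not self.records["event"].isin([0, 1]).all():
            raise UbipanError("event indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.records["event"].sum())


@dataclass
class ScreenThresholds:
    """Significance and fold-change bounds of the degradative-ubiquitination screen.

    Defaults follow the published screen: ubiquitination sites up at
    log2FC > 0 with q < 0.05; E3 up at log2FC >= 0.5 with q < 0.01;
    substrate protein down at log2FC < 0 with q < 0.01; substrate mRNA up
    at log2FC > 0 with q < 0.01.
    """

    site_fc_min: float = 0.0     # exclusive
    site_q_max: float = 0.05
    e3_fc_min: float = 0.5       # inclusive (criterion b)
    e3_q_max: float = 0.01
    prot_fc_max: float = 0.0     # exclusive (down branch)
    prot_q_max: float = 0.01
    rna_fc_min: float = 0.0      # exclusive (up branch)
    rna_q_max: float = 0.01
    min_sites: int = 1

    def __post_init__(self) -> None:
        for name in ("site_q_max", "e3_q_max", "prot_q_max", "rna_q_max"):
            q = getattr(self, name)
            if not (0 < q <= 1):
                raise UbipanError(f"{name} must be in (0, 1], got {q}")


def catalog_features(matrix: AbundanceMatrix, symbols: set[str]) -> list[str]:
    """Features of ``matrix`` that belong to ``symbols``, in matrix order."""
    return [f for f in matrix.feature_ids if f in symbols]


def site_parent(site_id: str) -> str:
    """Parent protein symbol of a ubiquitination-site id like ``"GENE_K123"``."""
    return site_id.rsplit("_K", 1)[0] if "_K" in site_id else site_id


def as_float_array(x, name: str = "values") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise UbipanError(f"{name} must be one-dimensional")
    return arr
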