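"""Readers and writers for the pipeline's plain-text formats.

Matrices are TSV with feature ids in the first column and sample ids in the
header; missing cells are written as ``NA`` and read from either ``NA`` or
an empty field.  Gene sets use GMT; pathways, networks and survival tables
are TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AbundanceMatrix,
    EnzymeCatalog,
    ESINetwork,
    GeneSetCollection,
    PathwayGraph,
    SurvivalTable,
    UbipanError,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("NA", "")

_SIGN_MAP = {"+1": 1, "1": 1, "-1": -1, "activation": 1, "inhibition": -1}


def read_abundance_matrix(path: str | Path, design_path: str | Path) -> AbundanceMatrix:
    """Read a features x samples TSV and its sample-design TSV."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise UbipanError(f"{path}: duplicate feature ids {dups[:5]}")
    if raw.columns.duplicated().any():
        raise UbipanError(f"{path}: duplicate sample ids in header")
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str),
                          dtype=float)
    for col in raw.columns:
        cells = raw[col]
        numeric = pd.to_numeric(cells.replace(dict.fromkeys(MISSING_TOKENS, np.nan)),
                                errors="coerce")
        bad = numeric.isna() & ~cells.isin(MISSING_TOKENS)
        if bad.any():
            row = cells.index[bad][0]
            raise UbipanError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}: "
                f"{cells[bad].iloc[0]!r}"
            )
        values[col] = numeric
    values.index.name = None
    design = read_design(design_path)
    return AbundanceMatrix(values, design)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "cohort", "condition"}
    missing = required - set(design.columns)
    if missing:
        raise UbipanError(f"{path}: design missing columns {sorted(missing)}")
    if "pair_id" not in design.columns:
        design["pair_id"] = ""
    design["pair_id"] = design["pair_id"].mask(design["pair_id"] == "", np.nan)
    if design["sample_id"].duplicated().any():
        raise UbipanError(f"{path}: duplicate sample_id in design")
    return design.set_index("sample_id")


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path,
                           design_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id",
                         float_format="%.17g")
    if design_path is not None:
        out = matrix.design.copy()
        out.index.name = "sample_id"
        out.to_csv(design_path, sep="\t", na_rep="")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_id <tab> description <tab> member1 <tab> ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise UbipanError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, name = fields[0], fields[1]
            if set_id in sets:
                raise UbipanError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = frozenset(m for m in fields[2:] if m)
            sets[set_id] = (name, members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, members) in collection.sets.items():
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def read_pathway_graphs(path: str | Path,
                        nodes_path: str | Path | None = None) -> list[PathwayGraph]:
    """Read signed pathway edge lists, one :class:`PathwayGraph` per pathway_id.

    ``nodes_path`` may supply a sidecar TSV (pathway_id, node) adding
    isolated nodes not touched by any edge.
    """
    edges = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "source", "target", "sign", "relation"}
    missing = required - set(edges.columns)
    if missing:
        raise UbipanError(f"{path}: pathway edges missing columns {sorted(missing)}")
    extra_nodes: dict[str, list[str]] = {}
    if nodes_path is not None:
        side = pd.read_csv(nodes_path, sep="\t", dtype=str)
        for pid, grp in side.groupby("pathway_id"):
            extra_nodes[pid] = list(grp["node"])
    graphs = []
    for pid, grp in edges.groupby("pathway_id", sort=True):
        node_order: dict[str, None] = {}
        parsed = []
        for _, row in grp.iterrows():
            raw_sign = str(row["sign"]).strip()
            if raw_sign not in _SIGN_MAP:
                raise UbipanError(
                    f"{path}: pathway {pid}: invalid sign {raw_sign!r} "
                    "(expected +1/-1/activation/inhibition)"
                )
            node_order.setdefault(row["source"])
            node_order.setdefault(row["target"])
            parsed.append((row["source"], row["target"], _SIGN_MAP[raw_sign],
                           row["relation"]))
        for node in extra_nodes.get(pid, []):
            node_order.setdefault(node)
        graphs.append(PathwayGraph(pid, list(node_order), parsed))
    return graphs


def write_pathway_graphs(graphs: list[PathwayGraph], path: str | Path) -> None:
    rows = [
        {"pathway_id": g.pathway_id, "source": s, "target": t, "sign": sign,
         "relation": rel}
        for g in graphs for s, t, sign, rel in g.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(e3_path: str | Path, dub_path: str | Path,
                 allow_overlap: bool = False) -> EnzymeCatalog:
    """Read E3 and DUB symbol lists, one symbol per line."""
    def read_list(p):
        with open(p) as fh:
            return {line.strip() for line in fh if line.strip()}
    return EnzymeCatalog(read_list(e3_path), read_list(dub_path), allow_overlap)


def write_catalog(catalog: EnzymeCatalog, e3_path: str | Path,
                  dub_path: str | Path) -> None:
    Path(e3_path).write_text("".join(f"{s}\n" for s in sorted(catalog.e3)))
    Path(dub_path).write_text("".join(f"{s}\n" for s in sorted(catalog.dub)))


def read_esi_network(path: str | Path) -> ESINetwork:
    """Read an E3-substrate edge list TSV with columns e3, substrate[, source]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"e3", "substrate"} <= set(df.columns):
        raise UbipanError(f"{path}: ESI network needs columns e3, substrate")
    source = df["source"] if "source" in df.columns else pd.Series("input", index=df.index)
    return ESINetwork({(r.e3, r.substrate, s)
                       for (_, r), s in zip(df.iterrows(), source)})


def write_esi_network(esi: ESINetwork, path: str | Path) -> None:
    rows = sorted(esi.edges)
    pd.DataFrame(rows, columns=["e3", "substrate", "source"]).to_csv(
        path, sep="\t", index=False)


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)
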