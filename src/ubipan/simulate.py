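"""Synthetic multi-omics cohort generation with planted ground truth.

The generator emulates the statistical structure of paired tumor/NAT
proteogenomic cohorts: log-ratio proteome matrices with subject random
effects and missing values, negative-binomial RNA counts tied to protein
baselines, protein-corrected ubiquitination-site matrices, an E3-substrate
interaction network, and survival linked to a marker protein.  Planted
effects (up-regulated E3s, down-regulated DUBs, degradative E3-substrate
pairs) are recorded in a :class:`GroundTruth` so every downstream stage can
be scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AbundanceMatrix,
    EnzymeCatalog,
    ESINetwork,
    PathwayGraph,
    SurvivalTable,
    UbipanError,
)


@dataclass
class CohortSpec:
    """Parameters of one synthetic paired tumor/NAT cohort.

    ``effect_log2fc`` is the mean planted tumor-vs-normal shift on the log2
    scale; ``noise_sd`` the per-cell residual SD; ``pair_sd`` the SD of the
    subject random effect shared by the two members of a pair.  Degradative
    E3-substrate pairs are planted with substrate sites up (+effect),
    substrate protein down (-effect) and substrate mRNA flat or up, with the
    targeting E3 among the up-regulated E3s.
    """

    n_pairs: int = 40
    n_proteins: int = 800
    n_e3: int = 60
    n_dub: int = 20
    frac_e3_up: float = 0.25
    frac_dub_down: float = 0.25
    esi_per_e3: int = 5
    frac_degradative: float = 0.1
    effect_log2fc: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    missing_mechanism: str = "MCAR"
    rna_dispersion: float = 0.1
    pair_sd: float = 0.3
    esi_coupling: float = 0.0
    decouple_tumor: bool = False
    survival_beta: float = 0.7
    cohort: str = "SYNTH"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_e3_up", "frac_dub_down", "frac_degradative",
                     "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise UbipanError(f"{name} must be in [0, 1], got {v}")
        if self.n_pairs < 3:
            raise UbipanError("n_pairs must be >= 3")
        if self.effect_log2fc <= 0:
            raise UbipanError("effect_log2fc must be > 0")
        if self.missing_mechanism not in ("MCAR", "intensity-dependent"):
            raise UbipanError(f"unknown missing mechanism {self.missing_mechanism!r}")
        if self.n_e3 + self.n_dub >= self.n_proteins:
            raise UbipanError("n_proteins must exceed n_e3 + n_dub")


@dataclass
class GroundTruth:
    """Planted directions and pairs of one simulated cohort."""

    protein_direction: pd.Series      # feature -> {-1, 0, +1}
    rna_direction: pd.Series          # gene -> {-1, 0, +1}
    site_direction: pd.Series         # site id -> {-1, 0, +1}
    degradative_pairs: set[tuple[str, str]]
    marker: str | None                # planted prognostic E3
    marker_log_hazard: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table (clearly test-only; never an analysis input)."""
        rows = [
            {"layer": "protein", "feature_id": f, "direction": int(d)}
            for f, d in self.protein_direction.items()
        ] + [
            {"layer": "rna", "feature_id": f, "direction": int(d)}
            for f, d in self.rna_direction.items()
        ] + [
            {"layer": "site", "feature_id": f, "direction": int(d)}
            for f, d in self.site_direction.items()
        ] + [
            {"layer": "degradative_pair", "feature_id": f"{e}->{s}", "direction": 1}
            for e, s in sorted(self.degradative_pairs)
        ]
        return pd.DataFrame(rows)


def _sample_design(spec: CohortSpec) -> pd.DataFrame:
    rows = []
    for i in range(spec.n_pairs):
        pid = f"{spec.cohort}_P{i + 1:03d}"
        rows.append({"sample_id": f"{spec.cohort}_T{i + 1:03d}",
                     "cohort": spec.cohort, "condition": "tumor", "pair_id": pid})
        rows.append({"sample_id": f"{spec.cohort}_N{i + 1:03d}",
                     "cohort": spec.cohort, "condition": "normal", "pair_id": pid})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_cohort(spec: CohortSpec) -> tuple[AbundanceMatrix, AbundanceMatrix,
                                               AbundanceMatrix, EnzymeCatalog,
                                               ESINetwork, GroundTruth]:
    """Simulate one paired cohort: proteome, RNA counts, sites, catalog, ESIs, truth.

    The site matrix is generated as already protein-corrected, i.e. the
    planted degradative site shift is net of the substrate's protein change.
    """
    rng = np.random.default_rng(spec.seed)
    e3s = [f"E3_{i + 1:04d}" for i in range(spec.n_e3)]
    dubs = [f"DUB_{i + 1:03d}" for i in range(spec.n_dub)]
    n_other = spec.n_proteins - spec.n_e3 - spec.n_dub
    others = [f"PROT_{i + 1:04d}" for i in range(n_other)]
    proteins = e3s + dubs + others
    catalog = EnzymeCatalog(set(e3s), set(dubs))

    # ESI network: esi_per_e3 substrates per E3, drawn from non-enzyme proteins
    if spec.esi_per_e3 > n_other:
        raise UbipanError("esi_per_e3 exceeds available substrate pool")
    edges = set()
    for e3 in e3s:
        subs = rng.choice(others, size=spec.esi_per_e3, replace=False)
        edges.update((e3, s, "planted") for s in subs)
    esi = ESINetwork(edges)

    # planted directions
    n_e3_up = round(spec.frac_e3_up * spec.n_e3)
    n_dub_down = round(spec.frac_dub_down * spec.n_dub)
    e3_up = list(rng.choice(e3s, size=n_e3_up, replace=False))
    dub_down = list(rng.choice(dubs, size=n_dub_down, replace=False))
    protein_shift = pd.Series(0.0, index=proteins)
    protein_shift[e3_up] = spec.effect_log2fc
    protein_shift[dub_down] = -spec.effect_log2fc

    # degradative pairs: edges whose E3 is planted up, distinct substrates
    eligible = [(e, s) for e, s, _ in sorted(esi.edges) if e in set(e3_up)]
    n_deg = round(spec.frac_degradative * len(esi.edges))
    rng.shuffle(eligible)
    degradative: set[tuple[str, str]] = set()
    used_subs: set[str] = set()
    for e, s in eligible:
        if len(degradative) >= n_deg:
            break
        if s in used_subs:
            continue
        degradative.add((e, s))
        used_subs.add(s)
    rna_shift = pd.Series(0.0, index=proteins)
    for _, s in degradative:
        protein_shift[s] = -spec.effect_log2fc
        # mRNA flat or up: never down, so protein loss is post-transcriptional
        rna_shift[s] = float(rng.choice([0.0, spec.effect_log2fc / 2]))
    # the degradative pattern is feature-level: every edge pairing an
    # up-regulated E3 with a degradative substrate carries it by construction
    e3_up_set = set(e3_up)
    degradative = {(e, s) for e, s, _ in esi.edges
                   if s in used_subs and e in e3_up_set}

    # proteome: baseline + subject effect + tumor shift + noise (+ ESI coupling)
    n = spec.n_pairs
    design = _sample_design(spec)
    tumor_cols = [f"{spec.cohort}_T{i + 1:03d}" for i in range(n)]
    normal_cols = [f"{spec.cohort}_N{i + 1:03d}" for i in range(n)]
    cols = tumor_cols + normal_cols
    baseline = rng.normal(0.0, 1.0, size=len(proteins))
    subject = rng.normal(0.0, spec.pair_sd, size=n)
    subject_row = np.concatenate([subject, subject])
    is_tumor = np.array([1.0] * n + [0.0] * n)
    noise = rng.normal(0.0, spec.noise_sd, size=(len(proteins), 2 * n))
    prot = (baseline[:, None] + subject_row[None, :]
            + protein_shift.to_numpy()[:, None] * is_tumor[None, :] + noise)
    prot = pd.DataFrame(prot, index=proteins, columns=cols)
    if spec.esi_coupling > 0:
        idx = {p: i for i, p in enumerate(proteins)}
        couple = np.ones(2 * n)
        if spec.decouple_tumor:
            couple = 1.0 - is_tumor
        for e, s, _ in sorted(esi.edges):
            prot.iloc[idx[s]] += spec.esi_coupling * noise[idx[e]] * couple

    # RNA counts: NB with mean tied to protein baseline, sample size factors
    size_factor = np.exp(rng.normal(0.0, 0.15, size=2 * n))
    log2_mu = (baseline[:, None] + 7.0
               + rna_shift.to_numpy()[:, None] * is_tumor[None, :])
    mu = (2.0 ** log2_mu) * size_factor[None, :]
    r = 1.0 / spec.rna_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    rna = pd.DataFrame(counts.astype(float), index=proteins, columns=cols)

    # ubiquitination sites: 1-3 per ESI substrate, degradative substrates shifted up
    site_ids, site_shift_list = [], []
    for sub in sorted(esi.substrates):
        n_sites = int(rng.integers(1, 4))
        shift = spec.effect_log2fc if sub in used_subs else 0.0
        for k in range(n_sites):
            site_ids.append(f"{sub}_K{(k + 1) * 11}")
            site_shift_list.append(shift)
    site_shift = pd.Series(site_shift_list, index=site_ids)
    site_base = rng.normal(0.0, 1.0, size=len(site_ids))
    site_noise = rng.normal(0.0, spec.noise_sd, size=(len(site_ids), 2 * n))
    site_vals = (site_base[:, None] + subject_row[None, :]
                 + site_shift.to_numpy()[:, None] * is_tumor[None, :] + site_noise)
    sites = pd.DataFrame(site_vals, index=site_ids, columns=cols)

    proteome = AbundanceMatrix(prot, design.copy())
    rna_mat = AbundanceMatrix(rna, design.copy())
    sites_mat = AbundanceMatrix(sites, design.copy())
    if spec.missing_rate > 0:
        proteome = mask_missing(proteome, spec.missing_rate, spec.missing_mechanism,
                                seed=int(rng.integers(2**31)))
        sites_mat = mask_missing(sites_mat, spec.missing_rate, spec.missing_mechanism,
                                 seed=int(rng.integers(2**31)))

    truth = GroundTruth(
        protein_direction=np.sign(protein_shift).astype(int),
        rna_direction=np.sign(rna_shift).astype(int),
        site_direction=np.sign(site_shift).astype(int),
        degradative_pairs=degradative,
        marker=e3_up[0] if e3_up else None,
        marker_log_hazard=spec.survival_beta,
    )
    return proteome, rna_mat, sites_mat, catalog, esi, truth


def mask_missing(matrix: AbundanceMatrix, rate: float, mechanism: str = "MCAR",
                 seed: int = 0) -> AbundanceMatrix:
    """Introduce missing values at the given expected rate.

    ``intensity-dependent`` masks low-abundance cells with higher probability
    (logistic weight in abundance, rescaled to the target mean rate), the
    dominant missingness mode of mass-spectrometry data.
    """
    if not (0 <= rate < 1):
        raise UbipanError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0:
        return matrix
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy(copy=True)
    observed = ~np.isnan(vals)
    if mechanism == "MCAR":
        prob = np.full(vals.shape, rate)
    elif mechanism == "intensity-dependent":
        x = np.where(observed, vals, np.nan)
        center = np.nanmedian(x)
        scale = max(np.nanstd(x), 1e-12)
        weight = 1.0 / (1.0 + np.exp((x - center) / scale))
        prob = rate * weight / np.nanmean(weight)
        prob = np.clip(np.nan_to_num(prob), 0.0, 0.95)
    else:
        raise UbipanError(f"unknown missing mechanism {mechanism!r}")
    mask = observed & (rng.random(vals.shape) < prob)
    vals[mask] = np.nan
    out = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return AbundanceMatrix(out, matrix.design.copy())


def simulate_survival(n: int, beta: float, censor_rate: float = 0.2,
                      seed: int = 0, base_hazard: float = 0.1) -> SurvivalTable:
    """Exponential survival with hazard proportional to exp(beta * marker)."""
    if n < 10:
        raise UbipanError("n must be >= 10")
    rng = np.random.default_rng(seed)
    marker = rng.normal(0.0, 1.0, size=n)
    return _survival_from_marker(marker, beta, censor_rate, rng, base_hazard)


def simulate_survival_from_marker(marker: np.ndarray, beta: float,
                                  censor_rate: float = 0.2, seed: int = 0,
                                  base_hazard: float = 0.1) -> SurvivalTable:
    """Survival table whose hazard follows a supplied marker vector."""
    rng = np.random.default_rng(seed)
    return _survival_from_marker(np.asarray(marker, float), beta, censor_rate,
                                 rng, base_hazard)


def _survival_from_marker(marker: np.ndarray, beta: float, censor_rate: float,
                          rng: np.random.Generator,
                          base_hazard: float) -> SurvivalTable:
    if censor_rate >= 1:
        raise UbipanError("censor_rate must be < 1")
    n = len(marker)
    hazard = base_hazard * np.exp(beta * marker)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        # independent exponential censoring tuned to the target rate at marker 0
        cens_hazard = base_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / cens_hazard, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    return SurvivalTable(pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "time": time, "event": event, "marker": marker,
    }))


def simulate_tissue_panel(n_cohorts: int = 6, n_tumor: int = 30, n_normal: int = 30,
                          n_features: int = 120, factor_scale: float = 1.5,
                          tumor_shared: bool = True, noise_sd: float = 0.6,
                          seed: int = 0) -> dict[str, AbundanceMatrix]:
    """Multi-cohort panel for the tissue-specificity clustering analysis.

    Normal samples carry a cohort-specific latent factor (tissue identity);
    tumor samples carry one factor shared across cohorts when
    ``tumor_shared`` (expression convergence under tumorigenesis), otherwise
    cohort-specific factors like the normals.
    """
    rng = np.random.default_rng(seed)
    features = [f"E3_{i + 1:04d}" for i in range(n_features)]
    shared_loading = rng.choice([-1.0, 1.0], size=n_features)
    out = {}
    for c in range(n_cohorts):
        name = f"C{c + 1:02d}"
        cohort_loading = rng.choice([-1.0, 1.0], size=n_features)
        cols, rows_design, blocks = [], [], []
        for j in range(n_tumor):
            sid = f"{name}_T{j + 1:03d}"
            loading = shared_loading if tumor_shared else cohort_loading
            f = abs(rng.normal(0.0, 1.0)) + 0.5
            blocks.append(factor_scale * f * loading
                          + rng.normal(0.0, noise_sd, n_features))
            cols.append(sid)
            rows_design.append({"sample_id": sid, "cohort": name,
                                "condition": "tumor", "pair_id": np.nan})
        for j in range(n_normal):
            sid = f"{name}_N{j + 1:03d}"
            f = abs(rng.normal(0.0, 1.0)) + 0.5
            blocks.append(factor_scale * f * cohort_loading
                          + rng.normal(0.0, noise_sd, n_features))
            cols.append(sid)
            rows_design.append({"sample_id": sid, "cohort": name,
                                "condition": "normal", "pair_id": np.nan})
        values = pd.DataFrame(np.column_stack(blocks), index=features, columns=cols)
        design = pd.DataFrame(rows_design).set_index("sample_id")
        out[name] = AbundanceMatrix(values, design)
    return out


def simulate_pathways(n_pathways: int, n_nodes: int = 12, edge_prob: float = 0.3,
                      frac_inhibition: float = 0.25, seed: int = 0,
                      node_pool: list[str] | None = None,
                      prefix: str = "PW") -> list[PathwayGraph]:
    """Random signed acyclic pathway topologies for testing and pipelines."""
    rng = np.random.default_rng(seed)
    graphs = []
    for p in range(n_pathways):
        if node_pool is not None:
            nodes = list(rng.choice(node_pool, size=n_nodes, replace=False))
        else:
            nodes = [f"{prefix}{p + 1}_G{i + 1:02d}" for i in range(n_nodes)]
        edges = []
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < edge_prob:
                    sign = -1 if rng.random() < frac_inhibition else 1
                    rel = "inhibition" if sign < 0 else "activation"
                    edges.append((nodes[i], nodes[j], sign, rel))
        if not edges:  # guarantee a connected spine
            edges = [(nodes[i], nodes[i + 1], 1, "activation")
                     for i in range(n_nodes - 1)]
        graphs.append(PathwayGraph(f"{prefix}{p + 1}", nodes, edges))
    return graphs


def activation_cascade(pathway_id: str, nodes: list[str]) -> PathwayGraph:
    """A pure activation chain node1 -> node2 -> ... (maximal signal propagation)."""
    edges = [(nodes[i], nodes[i + 1], 1, "activation") for i in range(len(nodes) - 1)]
    return PathwayGraph(pathway_id, list(nodes), edges)


def simulate_protective_cohort(n_samples: int = 100, n_proteins: int = 300,
                               n_pathway_nodes: int = 12, n_decoys: int = 5,
                               suppression: float = 1.0, beta: float = 1.0,
                               censor_rate: float = 0.2, noise_sd: float = 0.5,
                               seed: int = 0):
    """Tumor cohort with a protective E3 marker that suppresses one pathway.

    The marker protein's expression lowers the hazard (favorable prognosis)
    and down-regulates the nodes of one planted activation cascade in
    high-marker samples; decoy pathways are built from null proteins.

    Returns ``(proteome, survival, pathways, marker, planted_pathway_id)``.
    """
    rng = np.random.default_rng(seed)
    marker_name = "E3_MARKER"
    pathway_nodes = [f"PWNODE_{i + 1:02d}" for i in range(n_pathway_nodes)]
    n_null = n_proteins - 1 - n_pathway_nodes
    null_prots = [f"PROT_{i + 1:04d}" for i in range(n_null)]
    proteins = [marker_name] + pathway_nodes + null_prots
    cols = [f"S{i + 1:04d}" for i in range(n_samples)]

    marker = rng.normal(0.0, 1.0, size=n_samples)
    base = rng.normal(0.0, 1.0, size=len(proteins))
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(len(proteins), n_samples))
    vals[0] = marker
    for i in range(n_pathway_nodes):
        vals[1 + i] -= suppression * marker
    values = pd.DataFrame(vals, index=proteins, columns=cols)
    design = pd.DataFrame({"sample_id": cols, "cohort": "PROG",
                           "condition": "tumor", "pair_id": np.nan}
                          ).set_index("sample_id")
    proteome = AbundanceMatrix(values, design)

    survival = _survival_from_marker(marker, -beta, censor_rate, rng, 0.1)
    survival.records["sample_id"] = cols

    planted = activation_cascade("PW_PLANTED", pathway_nodes)
    decoys = []
    for d in range(n_decoys):
        nodes = list(rng.choice(null_prots, size=n_pathway_nodes, replace=False))
        decoys.append(activation_cascade(f"PW_DECOY{d + 1}", nodes))
    return proteome, survival, [planted] + decoys, marker_name, "PW_PLANTED"
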