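"""Tissue-specificity clustering of samples across cancer cohorts.

Per-cohort Z-score normalization removes batch effects, enzymes present in
every cohort are retained, PCA with a JackStraw permutation test selects
the components carrying signal, and samples are clustered by Louvain
community detection on a shared-nearest-neighbor (SNN) graph at a given
resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .types import AbundanceMatrix, EnzymeCatalog, UbipanError

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    component_pvalues: np.ndarray   # per component
    significant_components: list[int]


@dataclass
class ClusterAssignment:
    labels: pd.Series               # sample_id -> cluster label (0..)
    resolution: float
    k_neighbors: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def zscore_by_cohort(matrices: dict[str, AbundanceMatrix],
                     condition: str) -> AbundanceMatrix:
    """Z-score each cohort's condition samples per feature, then concatenate.

    Features are restricted to those shared by all cohorts; zero-SD features
    within a cohort are set to 0 there (logged).
    """
    if len(matrices) < 2:
        raise UbipanError("need >= 2 cohorts")
    shared: set[str] | None = None
    for m in matrices.values():
        shared = set(m.feature_ids) if shared is None else shared & set(m.feature_ids)
    if not shared:
        raise UbipanError("no shared features across cohorts")
    order = [f for f in next(iter(matrices.values())).feature_ids if f in shared]
    blocks, designs = [], []
    for cohort, m in matrices.items():
        samples = m.samples_of(condition)
        if len(samples) < 2:
            raise UbipanError(f"cohort {cohort!r}: need >= 2 {condition} samples "
                              "for Z-scoring")
        block = m.values.loc[order, samples]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero_sd = sd == 0
        if zero_sd.any():
            logger.warning("cohort %s: %d zero-SD features set to 0",
                           cohort, int(zero_sd.sum()))
        z = block.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
        blocks.append(z)
        designs.append(m.design.loc[samples])
    values = pd.concat(blocks, axis=1)
    design = pd.concat(designs)
    return AbundanceMatrix(values, design)


def intersect_features(matrices: dict[str, AbundanceMatrix],
                       catalog: EnzymeCatalog, which: str = "e3") -> list[str]:
    """Catalog enzymes present (some observed value) in every cohort."""
    if len(matrices) < 2:
        raise UbipanError("need >= 2 cohorts")
    wanted = catalog.e3 if which == "e3" else catalog.dub
    present: set[str] | None = None
    for m in matrices.values():
        obs = set(m.values.index[~m.values.isna().all(axis=1)]) & wanted
        present = obs if present is None else present & obs
    if not present:
        raise UbipanError(f"no {which} features present in all cohorts")
    return sorted(present)


def pca(matrix: AbundanceMatrix, n_components: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-centered PCA of samples; returns (scores, loadings)."""
    x = matrix.values.to_numpy().T  # samples x features
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    comp_cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=matrix.sample_ids,
                          columns=comp_cols)
    loadings = pd.DataFrame(vt[:k].T, index=matrix.feature_ids, columns=comp_cols)
    return scores, loadings


def jackstraw(matrix: AbundanceMatrix, n_components: int = 10,
              perm_frac: float = 0.01, n_perm: int = 100, alpha: float = 0.05,
              seed: int = 0) -> EmbeddingResult:
    """PCA with a permutation test for component significance.

    Each replicate permutes a random ``perm_frac`` of features across
    samples, re-runs PCA, and records the permuted features' loadings as the
    per-component null.  Feature p-values compare observed |loading| to the
    null pool; a component is significant when its feature p-values are
    stochastically smaller than uniform (one-sided KS, p < alpha).
    """
    n_feat = len(matrix.feature_ids)
    n_samp = len(matrix.sample_ids)
    if n_components >= min(n_feat, n_samp):
        raise UbipanError("n_components must be below min(n_features, n_samples)")
    m = int(round(perm_frac * n_feat))
    if m < 1:
        raise UbipanError(f"perm_frac {perm_frac} selects no feature out of {n_feat}")
    rng = np.random.default_rng(seed)
    scores, loadings = pca(matrix, n_components)
    k = loadings.shape[1]
    null_pools: list[list[np.ndarray]] = [[] for _ in range(k)]
    base = matrix.values.to_numpy()
    for _ in range(n_perm):
        perm = base.copy()
        chosen = rng.choice(n_feat, size=m, replace=False)
        for f in chosen:
            perm[f] = rng.permutation(perm[f])
        x = perm.T - perm.T.mean(axis=0)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        for c in range(k):
            null_pools[c].append(np.abs(vt[c, chosen]))
    pvals = np.empty(k)
    for c in range(k):
        null = np.concatenate(null_pools[c])
        obs = np.abs(loadings.iloc[:, c].to_numpy())
        # per-feature p, then one-sided KS against uniform
        feature_p = (1.0 + (null[None, :] >= obs[:, None]).sum(axis=1)) / (1.0 + null.size)
        pvals[c] = stats.ks_1samp(feature_p, stats.uniform.cdf,
                                  alternative="greater").pvalue
    significant = [c for c in range(k) if pvals[c] < alpha]
    return EmbeddingResult(scores, loadings, pvals, significant)


def snn_graph(scores: pd.DataFrame, k_neighbors: int = 20,
              prune: float = 1.0 / 15.0) -> nx.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets, pruned."""
    n = len(scores)
    if k_neighbors >= n:
        raise UbipanError(f"k_neighbors={k_neighbors} must be below n={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(scores.to_numpy())
    _, idx = nn.kneighbors(scores.to_numpy())
    neighbor_sets = [set(row) for row in idx]  # includes self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        candidates = set()
        for j in neighbor_sets[i]:
            candidates.update(idx[j])
        for j in candidates:
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w >= prune:
                g.add_edge(i, int(j), weight=w)
    return g


def snn_cluster(scores: pd.DataFrame, k_neighbors: int = 20,
                resolution: float = 0.8, seed: int = 0,
                prune: float = 1.0 / 15.0) -> ClusterAssignment:
    """Louvain community detection on the SNN graph of sample scores.

    Size-1 communities are merged into the nearest cluster by centroid
    distance; labels are contiguous from 0, ordered by decreasing size.
    """
    g = snn_graph(scores, k_neighbors=k_neighbors, prune=prune)
    comms = nx.community.louvain_communities(g, weight="weight",
                                             resolution=resolution, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    x = scores.to_numpy()
    big = [c for c in comms if len(c) > 1]
    singles = [c[0] for c in comms if len(c) == 1]
    if big and singles:
        centroids = np.array([x[c].mean(axis=0) for c in big])
        for s in singles:
            d = np.linalg.norm(centroids - x[s], axis=1)
            big[int(np.argmin(d))].append(s)
        logger.info("merged %d singleton samples into nearest clusters",
                    len(singles))
        comms = sorted((sorted(c) for c in big), key=lambda c: (-len(c), c[0]))
    labels = pd.Series(0, index=scores.index, name="cluster")
    for lab, members in enumerate(comms):
        labels.iloc[members] = lab
    return ClusterAssignment(labels, resolution, k_neighbors, seed)
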