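"""Rank-based differential expression between tumor and normal samples.

Paired cohorts use the Wilcoxon signed-rank test on within-pair differences;
unpaired cohorts the Wilcoxon rank-sum test.  RNA counts are normalized by
median-of-ratios size factors and then tested with the same rank tests.
P-values are Benjamini-Hochberg adjusted.  log2FC is the difference of
group means on the log2 scale (for counts, the log ratio of pseudo-counted
normalized means).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AbundanceMatrix, UbipanError

logger = logging.getLogger(__name__)

DIFFEXP_COLUMNS = ["feature_id", "log2FC", "p", "q", "test", "n_tumor", "n_normal"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise UbipanError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _signed_rank_p(diffs: np.ndarray) -> float:
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    try:
        return float(stats.wilcoxon(diffs, zero_method="wilcox",
                                    alternative="two-sided", method="auto").pvalue)
    except ValueError:
        return 1.0


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="auto").pvalue)


def test_differential(matrix: AbundanceMatrix, paired: bool) -> pd.DataFrame:
    """Per-feature tumor-vs-normal rank test with BH-adjusted q-values."""
    tumor = matrix.samples_of("tumor")
    normal = matrix.samples_of("normal")
    if not tumor or not normal:
        raise UbipanError("both tumor and normal samples are required")
    if paired:
        pairs = matrix.complete_pairs()
        if len(pairs) < 3:
            raise UbipanError("paired test requires >= 3 complete tumor/normal pairs")
        t_cols = [t for t, _ in pairs]
        n_cols = [n for _, n in pairs]
        tv = matrix.values[t_cols].to_numpy()
        nv = matrix.values[n_cols].to_numpy()
        rows = []
        for i, fid in enumerate(matrix.feature_ids):
            ok = ~np.isnan(tv[i]) & ~np.isnan(nv[i])
            d = tv[i, ok] - nv[i, ok]
            if d.size < 3:
                logger.warning("feature %s: <3 complete pairs; p set to 1", fid)
                p = 1.0
            else:
                p = _signed_rank_p(d)
            fc = float(np.mean(tv[i, ok]) - np.mean(nv[i, ok])) if ok.any() else 0.0
            rows.append((fid, fc, p, "signed_rank", int(ok.sum()), int(ok.sum())))
    else:
        tv = matrix.values[tumor].to_numpy()
        nv = matrix.values[normal].to_numpy()
        rows = []
        for i, fid in enumerate(matrix.feature_ids):
            a = tv[i][~np.isnan(tv[i])]
            b = nv[i][~np.isnan(nv[i])]
            if a.size == 0 or b.size == 0:
                p, fc = 1.0, 0.0
            else:
                p = _rank_sum_p(a, b)
                fc = float(a.mean() - b.mean())
            rows.append((fid, fc, p, "rank_sum", int(a.size), int(b.size)))
    table = pd.DataFrame(rows, columns=["feature_id", "log2FC", "p", "test",
                                        "n_tumor", "n_normal"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table[DIFFEXP_COLUMNS]


def normalize_counts(counts: AbundanceMatrix) -> AbundanceMatrix:
    """Median-of-ratios count normalization (size factor per sample)."""
    vals = counts.values.to_numpy()
    if np.isnan(vals).any() or (vals < 0).any():
        raise UbipanError("counts must be nonnegative and complete")
    all_positive = (vals > 0).all(axis=1)
    if not all_positive.any():
        raise UbipanError("no feature has positive counts in every sample")
    ref = vals[all_positive]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    normalized = vals / size_factors[None, :]
    return AbundanceMatrix(
        pd.DataFrame(normalized, index=counts.values.index,
                     columns=counts.values.columns),
        counts.design.copy())


def size_factors(counts: AbundanceMatrix) -> pd.Series:
    """Median-of-ratios size factors, exposed for diagnostics."""
    vals = counts.values.to_numpy()
    all_positive = (vals > 0).all(axis=1)
    if not all_positive.any():
        raise UbipanError("no feature has positive counts in every sample")
    ref = np.log(vals[all_positive])
    sf = np.exp(np.median(ref - ref.mean(axis=1)[:, None], axis=0))
    return pd.Series(sf, index=counts.values.columns)


def test_rna(counts: AbundanceMatrix, paired: bool) -> pd.DataFrame:
    """Differential expression of RNA counts on the normalized scale.

    log2FC uses pseudo-counted normalized group means; p-values come from
    the same rank tests as the proteome.
    """
    norm = normalize_counts(counts)
    base = test_differential(norm, paired=paired)
    tumor = norm.samples_of("tumor")
    normal = norm.samples_of("normal")
    mean_t = norm.values[tumor].mean(axis=1)
    mean_n = norm.values[normal].mean(axis=1)
    fc = np.log2((mean_t + 0.5) / (mean_n + 0.5))
    base["log2FC"] = fc.loc[base["feature_id"]].to_numpy()
    allzero = (counts.values == 0).all(axis=1)
    if allzero.any():
        zero_ids = base["feature_id"].isin(allzero.index[allzero])
        base.loc[zero_ids, ["log2FC", "p", "q"]] = [0.0, 1.0, 1.0]
        base["q"] = bh_adjust(base["p"].to_numpy())
    return base


def test_sites(sites: AbundanceMatrix) -> pd.DataFrame:
    """Signed-rank differential test of ubiquitination-site abundances.

    Site matrices are assumed protein-corrected; the design must be paired
    (the site test is defined on within-pair differences).
    """
    if len(sites.complete_pairs()) < 3:
        raise UbipanError("site testing requires a paired design "
                          "(>= 3 tumor/normal pairs)")
    return test_differential(sites, paired=True)
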