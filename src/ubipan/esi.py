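"""Proteome-based E3-substrate correlation analysis.

Spearman correlations between each E3 and its known substrates, a random
non-substrate background matched one draw per pair, and a two-sample
Kolmogorov-Smirnov comparison of correlation distributions (e.g. tumor vs
normal, or substrates vs background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import AbundanceMatrix, ESINetwork, UbipanError

logger = logging.getLogger(__name__)


@dataclass
class DistributionComparison:
    D: float
    p: float
    n_a: int
    n_b: int


def pairwise_spearman(matrix: AbundanceMatrix, pairs: ESINetwork, condition: str,
                      min_samples: int = 10,
                      is_substrate: bool = True) -> pd.DataFrame:
    """Spearman rho of each (E3, partner) pair over a condition's samples.

    Pairs with a member absent from the matrix are skipped; constant vectors
    yield a missing rho (logged).
    """
    samples = matrix.samples_of(condition)
    if len(samples) < min_samples:
        raise UbipanError(f"only {len(samples)} {condition} samples "
                          f"(min_samples={min_samples})")
    vals = matrix.values[samples]
    present = set(matrix.feature_ids)
    rows = []
    n_skipped = 0
    for e3, partner in pairs.pairs:
        if e3 not in present or partner not in present:
            n_skipped += 1
            continue
        x = vals.loc[e3].to_numpy()
        y = vals.loc[partner].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < min_samples:
            n_skipped += 1
            continue
        xa, ya = x[ok], y[ok]
        if np.all(xa == xa[0]) or np.all(ya == ya[0]):
            rho = np.nan
            logger.warning("constant vector for pair (%s, %s); rho undefined",
                           e3, partner)
        else:
            rho = float(stats.spearmanr(xa, ya).statistic)
        rows.append({"e3": e3, "partner": partner, "rho": rho,
                     "n_samples": int(ok.sum()), "condition": condition,
                     "is_substrate": is_substrate})
    if n_skipped:
        logger.info("pairwise_spearman: skipped %d pairs (absent member or "
                    "too few samples)", n_skipped)
    return pd.DataFrame(rows, columns=["e3", "partner", "rho", "n_samples",
                                       "condition", "is_substrate"])


def sample_random_background(pairs: ESINetwork, matrix: AbundanceMatrix,
                             esi: ESINetwork, seed: int = 0) -> ESINetwork:
    """One random non-substrate partner per pair, matched on the E3.

    Partners are drawn uniformly from the matrix's proteins excluding the
    E3 itself and all its known substrates (from the full ``esi`` network).
    """
    rng = np.random.default_rng(seed)
    proteins = sorted(matrix.feature_ids)
    counts: dict[str, int] = {}
    for e3, _ in pairs.pairs:
        counts[e3] = counts.get(e3, 0) + 1
    edges = set()
    n_skipped = 0
    for e3 in sorted(counts):
        excluded = esi.substrates_of(e3) | {e3}
        eligible = [p for p in proteins if p not in excluded]
        take = min(counts[e3], len(eligible))
        if take < counts[e3]:
            n_skipped += counts[e3] - take
            logger.warning("E3 %s: only %d eligible background partners for "
                           "%d pairs", e3, take, counts[e3])
        if take == 0:
            continue
        chosen = rng.choice(eligible, size=take, replace=False)
        edges.update((e3, partner, f"background_{k}")
                     for k, partner in enumerate(chosen))
    if n_skipped:
        logger.info("background sampling skipped %d pairs", n_skipped)
    return ESINetwork(edges, allow_self=False)


def compare_distributions(a: pd.DataFrame | np.ndarray,
                          b: pd.DataFrame | np.ndarray) -> DistributionComparison:
    """Two-sample KS comparison of correlation distributions.

    Accepts correlation tables (the ``rho`` column is used, missing values
    dropped) or raw numeric arrays.
    """
    xa = _rho_values(a)
    xb = _rho_values(b)
    if xa.size == 0 or xb.size == 0:
        raise UbipanError("empty correlation sample")
    res = stats.ks_2samp(xa, xb, method="asymp")
    return DistributionComparison(D=float(res.statistic), p=float(res.pvalue),
                                  n_a=int(xa.size), n_b=int(xb.size))


def _rho_values(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        v = x["rho"].to_numpy(dtype=float)
    else:
        v = np.asarray(x, dtype=float)
    return v[~np.isnan(v)]
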