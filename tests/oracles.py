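"""Independent brute-force oracles used to validate statistical kernels.

These deliberately avoid the implementation paths they check: exhaustive
enumeration for the rank tests, the literal step-up definition for BH,
direct pmf summation for the hypergeometric tail, ECDF scanning for KS,
and formula replay for Spearman and the biweight midcorrelation.
"""

import itertools
import math

import numpy as np
from scipy import stats


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_total = 2**n
    # null: each rank positive or negative with probability 1/2
    w_null = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in itertools.product([False, True], repeat=n)]
    mean_w = np.mean(w_null)
    extreme = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in w_null)
    return extreme / n_total


def rank_sum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    r_obs = ranks[:n_a].sum()
    idx = range(len(pooled))
    r_null = [ranks[list(c)].sum()
              for c in itertools.combinations(idx, n_a)]
    mean_r = np.mean(r_null)
    extreme = sum(abs(r - mean_r) >= abs(r_obs - mean_r) - 1e-12 for r in r_null)
    return extreme / len(r_null)


def bh_step_up(pvalues: np.ndarray) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{j >= i} m p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_tail_sum(overlap: int, universe: int, set_size: int,
                       query: int) -> float:
    """P[X >= overlap] as a direct sum of hypergeometric pmf terms."""
    total = 0.0
    for j in range(overlap, min(set_size, query) + 1):
        total += (math.comb(set_size, j) * math.comb(universe - set_size, query - j)
                  / math.comb(universe, query))
    return total


def ks_sup_distance(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x |ECDF_a(x) - ECDF_b(x)| scanned over the pooled points."""
    pooled = np.concatenate([a, b])
    return max(abs((a <= x).mean() - (b <= x).mean()) for x in pooled)


def spearman_via_rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def bicor_replay(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation computed directly from its definition."""
    def weights(v):
        med = np.median(v)
        u = (v - med) / (9 * np.median(np.abs(v - med)))
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    a = weights(np.asarray(x, float))
    b = weights(np.asarray(y, float))
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))
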