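"""Proteome-based prognosis: Cox models, maximally selected rank statistics,
Kaplan-Meier comparison, robust coexpression and substrate-mediated pathway
association.

The cutpoint model scores each candidate marker threshold by a standardized
two-group log-rank statistic built from log-rank (Nelson-Aalen) scores and
corrects for the maximal selection with a permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .diffexp import test_differential
from .types import AbundanceMatrix, SurvivalTable, UbipanError

logger = logging.getLogger(__name__)


@dataclass
class CoxResult:
    covariate: str
    beta: float
    hr: float
    se: float
    p: float
    n: int
    events: int


@dataclass
class CutpointResult:
    cutpoint: float
    max_stat: float
    p: float
    n_high: int
    n_low: int
    candidates: np.ndarray


def cox_fit(survival: SurvivalTable, covariate: np.ndarray | None = None,
            name: str = "marker") -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling, Wald p)."""
    df = survival.records.copy()
    if covariate is not None:
        df["marker"] = np.asarray(covariate, dtype=float)
    if df["event"].sum() < 2:
        raise UbipanError("cox_fit requires >= 2 events")
    if df["marker"].nunique() <= 1:
        raise UbipanError("covariate is constant")
    fitter = CoxPHFitter()
    try:
        fitter.fit(df[["time", "event", "marker"]], duration_col="time",
                   event_col="event")
    except ConvergenceError as err:
        raise UbipanError(f"Cox model failed to converge (separation?): {err}")
    s = fitter.summary.loc["marker"]
    return CoxResult(covariate=name, beta=float(s["coef"]),
                     hr=float(np.exp(s["coef"])), se=float(s["se(coef)"]),
                     p=float(s["p"]), n=len(df), events=int(df["event"].sum()))


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank (Savage) scores: event indicator minus the Nelson-Aalen
    cumulative hazard at each subject's time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    n = len(time)
    cumhaz_at = {}
    at_risk = n
    cum = 0.0
    i = 0
    t_sorted = time[order]
    e_sorted = event[order]
    while i < n:
        j = i
        d = 0
        while j < n and t_sorted[j] == t_sorted[i]:
            d += e_sorted[j]
            j += 1
        cum += d / at_risk
        cumhaz_at[t_sorted[i]] = cum
        at_risk -= (j - i)
        i = j
    return event - np.array([cumhaz_at[t] for t in time])


def maxstat_cutpoint(survival: SurvivalTable, marker: np.ndarray | None = None,
                     quantile_window: tuple[float, float] = (0.1, 0.9),
                     n_perm: int = 1000, min_group: int = 5,
                     seed: int = 0) -> CutpointResult:
    """Maximally selected log-rank statistic over candidate marker cutpoints.

    Candidates are observed marker values inside the quantile window leaving
    at least ``min_group`` samples per side; the p-value permutes marker
    labels and recomputes the maximum, with add-one smoothing.  The smallest
    cutpoint is taken on ties.
    """
    rec = survival.records
    m = np.asarray(rec["marker"] if marker is None else marker, dtype=float)
    if np.unique(m).size < 2:
        raise UbipanError("marker is constant")
    time = rec["time"].to_numpy()
    event = rec["event"].to_numpy()
    n = len(m)
    scores = logrank_scores(time, event)
    order = np.argsort(m, kind="stable")
    m_sorted = m[order]
    lo, hi = np.quantile(m, quantile_window)
    # split after position i puts samples 0..i in the low group
    positions = np.array([
        i for i in range(n - 1)
        if m_sorted[i] < m_sorted[i + 1]
        and lo <= m_sorted[i] <= hi
        and (i + 1) >= min_group and (n - i - 1) >= min_group
    ])
    if positions.size == 0:
        raise UbipanError("no candidate cutpoints inside the quantile window")
    a_bar = scores.mean()
    var_a = np.sum((scores - a_bar) ** 2)
    sizes = positions + 1.0

    def standardized_max(score_vec: np.ndarray) -> np.ndarray:
        cums = np.cumsum(score_vec)[positions]
        expect = sizes * a_bar
        var = sizes * (n - sizes) / (n * (n - 1.0)) * var_a
        return np.abs(cums - expect) / np.sqrt(var)

    z = standardized_max(scores[order])
    best = int(np.argmax(z))
    cutpoint = float(m_sorted[positions[best]])
    max_obs = float(z[best])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += standardized_max(rng.permutation(scores)).max() >= max_obs
    p = (exceed + 1.0) / (n_perm + 1.0)
    n_low = int(positions[best] + 1)
    return CutpointResult(cutpoint=cutpoint, max_stat=max_obs, p=float(p),
                          n_high=n - n_low, n_low=n_low,
                          candidates=m_sorted[positions])


def km_logrank(survival: SurvivalTable, groups: np.ndarray
               ) -> tuple[float, float, dict[str, pd.DataFrame]]:
    """Two-group log-rank test and Kaplan-Meier survival curves."""
    groups = np.asarray(groups)
    rec = survival.records
    labels = np.unique(groups)
    if len(labels) != 2:
        raise UbipanError("exactly two nonempty groups are required")
    res = multivariate_logrank_test(rec["time"], groups, rec["event"])
    curves = {}
    for lab in labels:
        mask = groups == lab
        km = KaplanMeierFitter().fit(rec.loc[mask, "time"],
                                     rec.loc[mask, "event"], label=str(lab))
        df = km.survival_function_.copy()
        df.columns = ["survival"]
        curves[str(lab)] = df
    return float(res.test_statistic), float(res.p_value), curves


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation with Pearson fallback when MAD is zero."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 10:
        raise UbipanError("bicor requires two equal-length vectors of size >= 10")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UbipanError("bicor requires non-constant vectors")
    tx = _biweight_transform(x)
    ty = _biweight_transform(y)
    if tx is None or ty is None:
        logger.warning("zero MAD; falling back to Pearson correlation")
        return float(np.corrcoef(x, y)[0, 1])
    return float(np.sum(tx * ty))


def _biweight_transform(v: np.ndarray) -> np.ndarray | None:
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return None
    u = (v - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    num = (v - med) * w
    return num / np.sqrt(np.sum(num**2))


def substrate_association(substrate: str, proteome: AbundanceMatrix,
                          top_n: int = 500) -> pd.DataFrame:
    """Proteins most strongly coexpressed with a substrate by |bicor|.

    The ranked (symbol, bicor) list feeds pathway impact analysis with the
    signed correlation as the per-gene score.
    """
    if substrate not in proteome.values.index:
        raise UbipanError(f"substrate {substrate!r} absent from proteome")
    x = proteome.values.loc[substrate].to_numpy()
    rows = []
    for symbol in proteome.feature_ids:
        if symbol == substrate:
            continue
        y = proteome.values.loc[symbol].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 10:
            continue
        try:
            rows.append({"symbol": symbol, "bicor": bicor(x[ok], y[ok])})
        except UbipanError:
            continue
    table = pd.DataFrame(rows)
    table["abs"] = table["bicor"].abs()
    table = table.sort_values(["abs", "symbol"], ascending=[False, True],
                              kind="stable").drop(columns="abs")
    return table.head(top_n).reset_index(drop=True)


def group_diffexp(proteome: AbundanceMatrix, high_group: np.ndarray,
                  fdr: float = 0.05, pronounced_fc: float = 2.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank-sum differential expression between marker-high and marker-low
    sample groups.

    log2FC is high minus low.  Returns (full table, significant q < fdr,
    pronounced subset with additionally |log2FC| >= pronounced_fc).
    """
    high_group = np.asarray(high_group, bool)
    if high_group.all() or not high_group.any():
        raise UbipanError("both groups must be nonempty")
    design = proteome.design.copy()
    design["condition"] = np.where(high_group, "tumor", "normal")
    design["pair_id"] = np.nan
    relabeled = AbundanceMatrix(proteome.values.copy(), design)
    table = test_differential(relabeled, paired=False)
    significant = table[table["q"] < fdr]
    pronounced = significant[significant["log2FC"].abs() >= pronounced_fc]
    return table, significant.reset_index(drop=True), pronounced.reset_index(drop=True)
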