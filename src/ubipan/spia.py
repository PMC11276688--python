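"""Signaling pathway impact analysis (SPIA) on signed topologies.

Combines two independent evidences per pathway: over-representation of
differential proteins (pNDE, hypergeometric tail) and the net topological
perturbation (tA, bootstrap pPERT).  Perturbation factors solve
PF = dE + B.PF with B[i, j] = sign(j -> i) / outdegree(j); the net
accumulation Acc = PF - dE sums to the pathway statistic tA, whose sign
labels the pathway Activated or Inhibited.  The two p-values merge by
Fisher's product method, pG = c - c ln c with c = pNDE * pPERT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import hypergeom_tail
from .diffexp import bh_adjust
from .types import PathwayGraph, UbipanError

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass
class PerturbationState:
    nodes: list[str]
    delta_e: np.ndarray
    pf: np.ndarray
    acc: np.ndarray
    t_a: float


def build_influence(graph: PathwayGraph) -> tuple[np.ndarray, np.ndarray]:
    """Normalized influence matrix B and per-node downstream counts.

    ``beta[i, j]`` is the sign of edge j -> i; B divides each column by the
    source's out-degree so a regulator's influence splits over its targets.
    """
    if not graph.nodes:
        raise UbipanError("empty pathway graph")
    index = {n: i for i, n in enumerate(graph.nodes)}
    n = len(graph.nodes)
    beta = np.zeros((n, n))
    for src, tgt, sign, _ in graph.edges:
        beta[index[tgt], index[src]] = float(sign)
    n_ds = (beta != 0).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(n_ds[None, :] > 0, beta / np.where(n_ds == 0, 1, n_ds)[None, :],
                     0.0)
    return b, n_ds


def net_perturbation(delta_e: np.ndarray, b: np.ndarray,
                     nodes: list[str] | None = None) -> PerturbationState:
    """Solve PF = dE + B.PF and accumulate the net perturbation."""
    delta_e = np.asarray(delta_e, dtype=float)
    n = b.shape[0]
    if delta_e.shape != (n,):
        raise UbipanError("delta_e length must match the influence matrix")
    i_minus_b = np.eye(n) - b
    try:
        pf = np.linalg.solve(i_minus_b, delta_e)
    except np.linalg.LinAlgError:
        logger.warning("singular (I - B); dampening influence by 0.99")
        pf = np.linalg.solve(np.eye(n) - 0.99 * b, delta_e)
    acc = pf - delta_e
    return PerturbationState(nodes or [str(i) for i in range(n)],
                             delta_e, pf, acc, float(acc.sum()))


def _accumulation_weights(b: np.ndarray) -> np.ndarray:
    """tA is linear in dE: tA = w . dE with w = ((I - B)^-T - I) 1."""
    n = b.shape[0]
    i_minus_b = np.eye(n) - b
    try:
        inv = np.linalg.inv(i_minus_b)
    except np.linalg.LinAlgError:
        inv = np.linalg.inv(np.eye(n) - 0.99 * b)
    return (inv - np.eye(n)).sum(axis=0)


def p_nde(n_de_on_pathway: int, pathway_size: int, n_de_total: int,
          universe_size: int) -> float:
    """Hypergeometric upper tail for the pathway's DE-gene count."""
    return hypergeom_tail(n_de_on_pathway, universe_size, pathway_size, n_de_total)


def p_pert(graph: PathwayGraph, observed_delta_e: dict[str, float],
           n_boot: int = 2000, seed: int = 0) -> tuple[float, np.ndarray, float]:
    """Bootstrap p-value of the observed net accumulation.

    Each replicate assigns the observed dE values to uniformly random
    pathway nodes and recomputes tA; the p-value is two-tailed around the
    null median with add-one smoothing.  Returns (pPERT, null tA sample,
    observed tA).
    """
    values = np.array([observed_delta_e[n] for n in graph.nodes
                       if n in observed_delta_e], dtype=float)
    nde = values.size
    if nde < 1:
        raise UbipanError("p_pert requires at least one DE node")
    n = graph.n_nodes
    if nde > n:
        raise UbipanError("more DE values than pathway nodes")
    b, _ = build_influence(graph)
    w = _accumulation_weights(b)
    de_vec = np.array([observed_delta_e.get(node, 0.0) for node in graph.nodes])
    t_obs = float(w @ de_vec)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for r in range(n_boot):
        nodes = rng.choice(n, size=nde, replace=False)
        null[r] = w[nodes] @ rng.permutation(values)
    med = np.median(null)
    extreme = np.abs(null - med) >= np.abs(t_obs - med)
    p = (extreme.sum() + 1.0) / (n_boot + 1.0)
    return float(p), null, t_obs


def combine_fisher(p_nde_val: float, p_pert_val: float) -> float:
    """Fisher product combination pG = c - c ln c, c = pNDE * pPERT."""
    for p in (p_nde_val, p_pert_val):
        if not (0 <= p <= 1):
            raise UbipanError(f"p-value out of range: {p}")
    c = p_nde_val * p_pert_val
    if c == 0:
        logger.warning("zero combined probability clamped to machine minimum")
        c = _TINY
    return float(c - c * np.log(c))


def run_spia(de_table: pd.DataFrame, all_measured: list[str],
             pathways: list[PathwayGraph], n_boot: int = 2000,
             seed: int = 0) -> pd.DataFrame:
    """SPIA over a list of pathways given a (symbol, log2FC) DE table.

    Any signed per-gene score may stand in for log2FC (e.g. robust
    correlations for substrate-mediated association).  Pathways without DE
    nodes are reported with pNDE = 1, tA = 0, pPERT = 1.
    """
    if not pathways:
        raise UbipanError("empty pathway list")
    if not {"symbol", "log2FC"} <= set(de_table.columns):
        raise UbipanError("de_table needs columns symbol, log2FC")
    measured = set(all_measured)
    if not set(de_table["symbol"]) <= measured:
        raise UbipanError("DE symbols must be a subset of all_measured")
    de = dict(zip(de_table["symbol"], de_table["log2FC"].astype(float)))
    rows = []
    for k, graph in enumerate(pathways):
        nodes_measured = [n for n in graph.nodes if n in measured]
        de_nodes = [n for n in nodes_measured if n in de]
        nde = len(de_nodes)
        if nde == 0:
            rows.append({"pathway_id": graph.pathway_id, "NDE": 0,
                         "pathway_size": len(nodes_measured), "pNDE": 1.0,
                         "tA": 0.0, "pPERT": 1.0, "pG": combine_fisher(1.0, 1.0),
                         "status": "Inhibited"})
            continue
        pnde = p_nde(nde, len(nodes_measured), len(de), len(measured))
        obs = {n: de[n] for n in de_nodes}
        ppert, _, t_obs = p_pert(graph, obs, n_boot=n_boot,
                                 seed=int(np.random.default_rng([seed, k])
                                          .integers(2**31)))
        rows.append({"pathway_id": graph.pathway_id, "NDE": nde,
                     "pathway_size": len(nodes_measured), "pNDE": pnde,
                     "tA": t_obs, "pPERT": ppert,
                     "pG": combine_fisher(pnde, ppert),
                     "status": "Activated" if t_obs > 0 else "Inhibited"})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["pG"].to_numpy())
    table["bonferroni"] = np.minimum(table["pG"] * len(table), 1.0)
    table["neg_log_pNDE"] = -np.log10(table["pNDE"])
    table["neg_log_pPERT"] = -np.log10(table["pPERT"])
    return table.sort_values("pG", kind="stable").reset_index(drop=True)
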