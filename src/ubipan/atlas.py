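"""Pan-cancer regulatory atlas of E3/DUB expression changes.

Builds the cohort-wise up/down tallies, the signed column-scaled log2FC
matrix (positives scaled to (0, 1], negatives to [-1, 0) per cohort), Ward
("ward.D2") row clustering, and hypergeometric pathway over-representation
per cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .diffexp import bh_adjust
from .types import EnzymeCatalog, GeneSetCollection, UbipanError

logger = logging.getLogger(__name__)


def tally_regulation(tables: dict[str, pd.DataFrame],
                     catalog: EnzymeCatalog) -> pd.DataFrame:
    """Counts of up/down-regulated catalog enzymes per cohort (sign of log2FC).

    Zero log2FC counts in neither direction.
    """
    if not tables:
        raise UbipanError("no cohort tables supplied")
    rows = []
    for cohort, table in tables.items():
        if not isinstance(table, pd.DataFrame) or "log2FC" not in table.columns:
            raise UbipanError(f"cohort {cohort!r}: not a differential table")
        sub = table.set_index("feature_id")["log2FC"]
        e3 = sub[sub.index.isin(catalog.e3)]
        dub = sub[sub.index.isin(catalog.dub)]
        rows.append({
            "cohort": cohort,
            "e3_up": int((e3 > 0).sum()), "e3_down": int((e3 < 0).sum()),
            "dub_up": int((dub > 0).sum()), "dub_down": int((dub < 0).sum()),
        })
    return pd.DataFrame(rows).set_index("cohort")


def log2fc_matrix(tables: dict[str, pd.DataFrame], features: list[str]) -> pd.DataFrame:
    """Assemble an enzymes x cohorts log2FC matrix (NaN where absent)."""
    out = pd.DataFrame(index=features, columns=list(tables), dtype=float)
    for cohort, table in tables.items():
        sub = table.set_index("feature_id")["log2FC"]
        out[cohort] = sub.reindex(features)
    return out


def signed_column_scale(log2fc: pd.DataFrame) -> pd.DataFrame:
    """Scale each column's positives to (0, 1] and negatives to [-1, 0).

    Zeros stay zero and missing entries stay missing, so each cohort's
    strongest up- and down-regulation map to +1 and -1 respectively.
    """
    out = log2fc.copy().astype(float)
    for col in out.columns:
        v = out[col]
        if v.isna().all():
            raise UbipanError(f"column {col!r} is all-missing")
        pos_max = v[v > 0].max()
        neg_min = v[v < 0].min()
        scaled = v.copy()
        if pd.notna(pos_max):
            scaled[v > 0] = v[v > 0] / pos_max
        if pd.notna(neg_min):
            scaled[v < 0] = v[v < 0] / abs(neg_min)
        out[col] = scaled
    return out


def ward_cluster(matrix: pd.DataFrame, k_rows: int = 3
                 ) -> tuple[pd.Series, list[str], np.ndarray]:
    """Ward-linkage row clustering (the 'ward.D2' convention: Euclidean
    distances, squared inside the merge criterion).

    Missing cells are imputed to 0 for the distance computation only.
    Returns (labels indexed by row id, dendrogram leaf order, linkage matrix).
    """
    if k_rows < 2:
        raise UbipanError("k_rows must be >= 2")
    if k_rows > matrix.shape[0]:
        raise UbipanError(f"k_rows={k_rows} exceeds number of rows "
                          f"({matrix.shape[0]})")
    x = matrix.fillna(0.0).to_numpy()
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(link, t=k_rows, criterion="maxclust")
    # relabel clusters 0.. in order of first appearance for determinism
    mapping: dict[int, int] = {}
    labels = []
    for lab in raw:
        mapping.setdefault(lab, len(mapping))
        labels.append(mapping[lab])
    leaf_order = [matrix.index[i] for i in hierarchy.leaves_list(link)]
    return pd.Series(labels, index=matrix.index, name="cluster"), leaf_order, link


def hypergeom_tail(overlap: int, universe: int, set_size: int, query: int) -> float:
    """Upper-tail hypergeometric probability P[X >= overlap]."""
    if overlap > min(set_size, query) or set_size > universe or query > universe:
        raise UbipanError("inconsistent hypergeometric counts")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def ora_enrich(query: set[str], universe: set[str],
               sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a query list."""
    if not universe:
        raise UbipanError("empty universe")
    if not set(query) <= set(universe):
        raise UbipanError("query must be a subset of the universe")
    query = set(query)
    rows = []
    for set_id, (name, members) in sets.sets.items():
        members_u = frozenset(members) & universe
        if not members_u:
            continue
        overlap = query & members_u
        p = hypergeom_tail(len(overlap), len(universe), len(members_u), len(query))
        rows.append({
            "set_id": set_id, "name": name, "overlap": len(overlap),
            "set_size": len(members_u), "universe_size": len(universe),
            "n_query": len(query), "p": p, "members": ",".join(sorted(overlap)),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table = pd.DataFrame(columns=["set_id", "name", "overlap", "set_size",
                                      "universe_size", "n_query", "p", "members",
                                      "q"])
    return table
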