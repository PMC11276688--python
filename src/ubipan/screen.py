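"""Multi-omics screening of E3-substrate interactions.

An interaction is called *over-ubiquitinated* when (a) the substrate has at
least one up-regulated ubiquitination site (log2FC > 0, q < 0.05) and (b)
a known targeting E3 is up-regulated at the protein level (log2FC >= 0.5,
q < 0.01).  It is further called *degradative* when (c) the substrate's
protein level drops (log2FC < 0, q < 0.01) while its mRNA is not
significantly down, or the protein shows no significant change while the
mRNA significantly rises — the signature of ubiquitin-driven proteasomal
degradation rather than transcriptional loss.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import EnzymeCatalog, ESINetwork, ScreenThresholds, UbipanError, site_parent

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "e3", "substrate", "call", "branch", "evidence_sites",
    "site_log2FC", "site_q", "e3_log2FC", "e3_q",
    "prot_log2FC", "prot_q", "rna_log2FC", "rna_q", "skip_reason",
]


def select_significant_e3(prot_de: pd.DataFrame,
                          catalog: EnzymeCatalog) -> dict[str, list[str]]:
    """Significantly differential catalog E3s: q < 0.01 and |log2FC| > 0.5."""
    if prot_de.empty:
        return {"up": [], "down": []}
    sub = prot_de[prot_de["feature_id"].isin(catalog.e3)]
    sig = sub[(sub["q"] < 0.01) & (sub["log2FC"].abs() > 0.5)]
    return {
        "up": sorted(sig.loc[sig["log2FC"] > 0, "feature_id"]),
        "down": sorted(sig.loc[sig["log2FC"] < 0, "feature_id"]),
    }


def classify_esi(e3: str, substrate: str, site_rows: pd.DataFrame,
                 e3_row: pd.Series | None, prot_row: pd.Series | None,
                 rna_row: pd.Series | None,
                 thresholds: ScreenThresholds = ScreenThresholds()) -> dict:
    """Evaluate one E3-substrate pair against the screen criteria.

    ``site_rows`` holds the substrate's site-level statistics; ``e3_row``,
    ``prot_row`` and ``rna_row`` the E3 protein, substrate protein and
    substrate mRNA rows.  A missing layer yields a skipped call with a
    layer-specific reason code.
    """
    t = thresholds
    out = {c: np.nan for c in SCREEN_COLUMNS}
    out.update({"e3": e3, "substrate": substrate, "call": "none",
                "branch": "none", "evidence_sites": "", "skip_reason": ""})
    if site_rows is None or len(site_rows) == 0:
        out["skip_reason"] = "no_site_data"
        return out
    if e3_row is None:
        out["skip_reason"] = "no_e3_protein_data"
        return out
    if prot_row is None:
        out["skip_reason"] = "no_substrate_protein_data"
        return out
    if rna_row is None:
        out["skip_reason"] = "no_substrate_rna_data"
        return out

    passing = site_rows[(site_rows["log2FC"] > t.site_fc_min)
                        & (site_rows["q"] < t.site_q_max)]
    crit_a = len(passing) >= t.min_sites
    crit_b = (e3_row["log2FC"] >= t.e3_fc_min) and (e3_row["q"] < t.e3_q_max)

    if len(passing):
        best = passing.loc[passing["q"].idxmin()]
        out["evidence_sites"] = ",".join(sorted(passing["feature_id"]))
    else:
        best = site_rows.loc[site_rows["q"].idxmin()]
    out.update({"site_log2FC": float(best["log2FC"]), "site_q": float(best["q"]),
                "e3_log2FC": float(e3_row["log2FC"]), "e3_q": float(e3_row["q"]),
                "prot_log2FC": float(prot_row["log2FC"]),
                "prot_q": float(prot_row["q"]),
                "rna_log2FC": float(rna_row["log2FC"]),
                "rna_q": float(rna_row["q"])})
    if not (crit_a and crit_b):
        return out

    rna_sig_down = (rna_row["log2FC"] < 0) and (rna_row["q"] < t.rna_q_max)
    branch1 = ((prot_row["log2FC"] < t.prot_fc_max)
               and (prot_row["q"] < t.prot_q_max)
               and not rna_sig_down)
    branch2 = ((prot_row["q"] >= t.prot_q_max)
               and (rna_row["log2FC"] > t.rna_fc_min)
               and (rna_row["q"] < t.rna_q_max))
    if branch1 or branch2:
        out["call"] = "degradative"
        out["branch"] = ("protein_down_mrna_not_down" if branch1
                         else "protein_flat_mrna_up")
    else:
        out["call"] = "over_ubiquitinated"
    return out


def run_screen(esi: ESINetwork, site_de: pd.DataFrame, prot_de: pd.DataFrame,
               rna_de: pd.DataFrame, catalog: EnzymeCatalog,
               thresholds: ScreenThresholds = ScreenThresholds()
               ) -> tuple[pd.DataFrame, dict]:
    """Evaluate every ESI edge; return the call table and summary counts."""
    if not esi.edges:
        raise UbipanError("empty ESI network")
    for name, table in (("site", site_de), ("protein", prot_de), ("rna", rna_de)):
        if table is None or not isinstance(table, pd.DataFrame) or table.empty:
            raise UbipanError(f"missing {name} differential-expression layer")
    site_de = site_de.assign(parent=[site_parent(f) for f in site_de["feature_id"]])
    sites_by_parent = dict(tuple(site_de.groupby("parent")))
    prot_by_id = prot_de.set_index("feature_id")
    rna_by_id = rna_de.set_index("feature_id")

    def row_or_none(table: pd.DataFrame, key: str):
        return table.loc[key] if key in table.index else None

    rows = []
    for e3, substrate in esi.pairs:
        rows.append(classify_esi(
            e3, substrate,
            sites_by_parent.get(substrate),
            row_or_none(prot_by_id, e3),
            row_or_none(prot_by_id, substrate),
            row_or_none(rna_by_id, substrate),
            thresholds))
    table = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    over = table[table["call"].isin(["over_ubiquitinated", "degradative"])]
    deg = table[table["call"] == "degradative"]
    summary = {
        "n_pairs": len(table),
        "n_skipped": int((table["skip_reason"] != "").sum()),
        "over_ubiquitinated": {"n_pairs": len(over),
                               "n_e3": int(over["e3"].nunique()),
                               "n_substrates": int(over["substrate"].nunique())},
        "degradative": {"n_pairs": len(deg),
                        "n_e3": int(deg["e3"].nunique()),
                        "n_substrates": int(deg["substrate"].nunique())},
    }
    return table, summary
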