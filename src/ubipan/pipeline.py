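"""End-to-end synthetic-cohort pipeline driver.

Runs the eight analytic stages (impute, diffexp, atlas, cluster, esi_corr,
screen, spia, prognosis) on a generated multi-cohort data set, writing every
stage's tables as TSV plus a manifest recording the seed, thresholds and
stage outputs.  Stages are also callable individually (see :mod:`ubipan.cli`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, atlas, clusters, diffexp, esi, missing, prognosis, screen, spia
from .config import PipelineConfig
from .io import (
    write_abundance_matrix,
    write_catalog,
    write_esi_network,
    write_pathway_graphs,
    write_survival,
)
from .simulate import (
    CohortSpec,
    simulate_cohort,
    simulate_pathways,
    simulate_survival_from_marker,
)
from .types import UbipanError

logger = logging.getLogger(__name__)

ANALYTIC_STAGES = ["impute", "diffexp", "atlas", "cluster", "esi_corr",
                   "screen", "spia", "prognosis"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Simulate a multi-cohort study and run all analytic stages.

    Returns the output directory; raises on any stage failure after logging
    the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "thresholds": asdict(config.thresholds),
                      "cohort_spec": asdict(config.cohort), "stages": {}}
    stage = "simulate"
    try:
        data = _simulate_all(config, out)
        manifest["stages"]["simulate"] = {"cohorts": sorted(data["proteomes"])}
        for stage in ANALYTIC_STAGES:
            outputs = _STAGE_FUNCS[stage](config, data, out)
            manifest["stages"][stage] = outputs
            logger.info("stage %s complete", stage)
    except Exception as err:
        logger.error("stage %s failed: %s", stage, err)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _cohort_name(i: int) -> str:
    return f"C{i + 1:02d}"


def _simulate_all(config: PipelineConfig, out: Path) -> dict:
    data: dict = {"proteomes": {}, "truths": {}}
    for i in range(config.n_cohorts):
        name = _cohort_name(i)
        spec_kwargs = asdict(config.cohort)
        spec_kwargs.update(cohort=name, seed=config.seed + i)
        prot, rna, sites, catalog, esi_net, truth = simulate_cohort(
            CohortSpec(**spec_kwargs))
        data["proteomes"][name] = prot
        data["truths"][name] = truth
        if i == 0:  # main cohort carries the RNA/site layers and network
            data.update(main=name, rna=rna, sites=sites, catalog=catalog,
                        esi=esi_net)
        write_abundance_matrix(prot, out / f"proteome_{name}.tsv",
                               out / f"design_{name}.tsv")
        truth.to_frame().to_csv(out / f"truth_{name}.TEST_ONLY.tsv", sep="\t",
                                index=False)
    write_abundance_matrix(data["rna"], out / "rna_counts.tsv")
    write_abundance_matrix(data["sites"], out / "sites.tsv")
    write_catalog(data["catalog"], out / "e3_catalog.txt", out / "dub_catalog.txt")
    write_esi_network(data["esi"], out / "esi_network.tsv")
    return data


def _stage_impute(config, data, out):
    imputed = {}
    for name, prot in data["proteomes"].items():
        filt = missing.filter_missing(prot)
        imputed[name] = missing.impute(filt, method="ensemble", k=10,
                                       seed=config.seed)
        write_abundance_matrix(imputed[name], out / f"proteome_imputed_{name}.tsv")
    data["imputed"] = imputed
    sites = missing.impute(missing.filter_missing(data["sites"]),
                           method="ensemble", k=10, seed=config.seed)
    data["sites_imputed"] = sites
    write_abundance_matrix(sites, out / "sites_imputed.tsv")
    return {"files": [f"proteome_imputed_{n}.tsv" for n in imputed]}


def _stage_diffexp(config, data, out):
    de = {}
    for name, mat in data["imputed"].items():
        de[name] = diffexp.test_differential(mat, paired=True)
        de[name].to_csv(out / f"diffexp_protein_{name}.tsv", sep="\t", index=False)
    data["prot_de"] = de
    data["rna_de"] = diffexp.test_rna(data["rna"], paired=True)
    data["rna_de"].to_csv(out / "diffexp_rna.tsv", sep="\t", index=False)
    data["site_de"] = diffexp.test_sites(data["sites_imputed"])
    data["site_de"].to_csv(out / "diffexp_sites.tsv", sep="\t", index=False)
    return {"cohorts": sorted(de)}


def _stage_atlas(config, data, out):
    catalog = data["catalog"]
    tally = atlas.tally_regulation(data["prot_de"], catalog)
    tally.to_csv(out / "atlas_tally.tsv", sep="\t")
    enzymes = sorted(catalog.e3 | catalog.dub)
    fc = atlas.log2fc_matrix(data["prot_de"], enzymes)
    scaled = atlas.signed_column_scale(fc)
    scaled.to_csv(out / "atlas_scaled.tsv", sep="\t", na_rep="NA")
    labels, order, _ = atlas.ward_cluster(scaled, k_rows=config.atlas_k_rows)
    labels.to_frame().to_csv(out / "atlas_clusters.tsv", sep="\t")
    # over-representation of each row cluster within the enzyme universe,
    # against gene sets built from catalog blocks
    sets = _catalog_gene_sets(catalog)
    enrich_frames = []
    universe = set(enzymes)
    for lab in sorted(labels.unique()):
        query = set(labels.index[labels == lab])
        table = atlas.ora_enrich(query, universe, sets)
        table.insert(0, "cluster", lab)
        enrich_frames.append(table)
    pd.concat(enrich_frames).to_csv(out / "atlas_enrichment.tsv", sep="\t",
                                    index=False)
    return {"n_clusters": int(labels.nunique())}


def _catalog_gene_sets(catalog):
    from .types import GeneSetCollection
    e3 = sorted(catalog.e3)
    dub = sorted(catalog.dub)
    sets = {}
    block = max(5, len(e3) // 4)
    for i in range(0, len(e3), block):
        sets[f"E3_SET_{i // block + 1}"] = (f"E3 block {i // block + 1}",
                                            frozenset(e3[i:i + block]))
    sets["DUB_SET_1"] = ("all DUBs", frozenset(dub))
    return GeneSetCollection(sets)


def _stage_cluster(config, data, out):
    results = {}
    for cond, resolution in (("tumor", config.resolution_tumor),
                             ("normal", config.resolution_normal)):
        shared = clusters.intersect_features(data["imputed"], data["catalog"], "e3")
        merged = clusters.zscore_by_cohort(
            {n: m.subset_features(shared) for n, m in data["imputed"].items()}, cond)
        emb = clusters.jackstraw(merged, n_components=config.n_components,
                                 perm_frac=config.jackstraw_frac,
                                 n_perm=config.jackstraw_perm, seed=config.seed)
        sig = emb.significant_components or [0]
        assign = clusters.snn_cluster(emb.scores.iloc[:, sig],
                                      k_neighbors=config.k_neighbors,
                                      resolution=resolution, seed=config.seed)
        emb.scores.to_csv(out / f"embedding_{cond}.tsv", sep="\t")
        assign.labels.to_frame().to_csv(out / f"clusters_{cond}.tsv", sep="\t")
        results[cond] = assign.n_clusters
    return {"n_clusters": results}


def _stage_esi_corr(config, data, out):
    main = data["imputed"][data["main"]]
    frames, comps = [], []
    fg = {}
    for cond in ("tumor", "normal"):
        fore = esi.pairwise_spearman(main, data["esi"], cond)
        bg_net = esi.sample_random_background(data["esi"], main, data["esi"],
                                              seed=config.seed)
        back = esi.pairwise_spearman(main, bg_net, cond, is_substrate=False)
        frames += [fore, back]
        fg[cond] = fore
        comp = esi.compare_distributions(fore, back)
        comps.append({"cohort": data["main"], "condition": cond,
                      "comparison": "substrate_vs_background",
                      "D": comp.D, "p": comp.p, "n_a": comp.n_a, "n_b": comp.n_b})
    tn = esi.compare_distributions(fg["tumor"], fg["normal"])
    comps.append({"cohort": data["main"], "condition": "tumor_vs_normal",
                  "comparison": "substrate", "D": tn.D, "p": tn.p,
                  "n_a": tn.n_a, "n_b": tn.n_b})
    corr = pd.concat(frames)
    corr.to_csv(out / "esi_correlations.tsv", sep="\t", index=False)
    comp_table = pd.DataFrame(comps)
    comp_table["q"] = diffexp.bh_adjust(comp_table["p"].to_numpy())
    comp_table.to_csv(out / "esi_comparisons.tsv", sep="\t", index=False)
    return {"n_correlations": len(corr)}


def _stage_screen(config, data, out):
    if "site_de" not in data or data["site_de"] is None:
        raise UbipanError("screen stage requires the ubiquitylome layer (site_de)")
    table, summary = screen.run_screen(
        data["esi"], data["site_de"], data["prot_de"][data["main"]],
        data["rna_de"], data["catalog"], config.thresholds)
    table.to_csv(out / "screen_calls.tsv", sep="\t", index=False)
    (out / "screen_summary.json").write_text(json.dumps(summary, indent=2))
    data["screen"] = table
    return summary


def _stage_spia(config, data, out):
    prot_de = data["prot_de"][data["main"]]
    sig = prot_de[(prot_de["q"] < 0.05)].nlargest(100, "log2FC",
                                                  keep="all")
    de_table = sig.rename(columns={"feature_id": "symbol"})[["symbol", "log2FC"]]
    pool = list(prot_de["feature_id"])
    pathways = simulate_pathways(6, n_nodes=12, seed=config.seed, node_pool=pool)
    result = spia.run_spia(de_table, pool, pathways, n_boot=config.n_boot,
                           seed=config.seed)
    result.to_csv(out / "spia.tsv", sep="\t", index=False)
    return {"n_pathways": len(result)}


def _stage_prognosis(config, data, out):
    main = data["imputed"][data["main"]]
    truth = data["truths"][data["main"]]
    marker = truth.marker
    if marker is None or marker not in main.values.index:
        raise UbipanError("no planted prognostic marker in the main cohort")
    tumor = main.samples_of("tumor")
    marker_vals = main.values.loc[marker, tumor].to_numpy()
    surv = simulate_survival_from_marker(marker_vals, truth.marker_log_hazard,
                                         censor_rate=config.censor_rate,
                                         seed=config.seed)
    surv.records["sample_id"] = tumor
    write_survival(surv, out / "survival.tsv")
    cox = prognosis.cox_fit(surv, name=marker)
    cut = prognosis.maxstat_cutpoint(surv, n_perm=config.n_perm, seed=config.seed)
    high = surv.records["marker"].to_numpy() > cut.cutpoint
    chi2, km_p, _ = prognosis.km_logrank(surv, high.astype(int))
    tumor_mat = main.subset_samples(tumor)
    _, significant, pronounced = prognosis.group_diffexp(tumor_mat, high)
    significant.to_csv(out / "group_diffexp_significant.tsv", sep="\t", index=False)
    pronounced.to_csv(out / "group_diffexp_pronounced.tsv", sep="\t", index=False)
    assoc = prognosis.substrate_association(marker, tumor_mat,
                                            top_n=config.top_n_association)
    assoc.to_csv(out / "substrate_association.tsv", sep="\t", index=False)
    summary = {"marker": marker, "cox": asdict(cox),
               "cutpoint": {"cutpoint": cut.cutpoint, "max_stat": cut.max_stat,
                            "p": cut.p, "n_high": cut.n_high, "n_low": cut.n_low},
               "km": {"chi_square": chi2, "p": km_p},
               "n_significant": len(significant), "n_pronounced": len(pronounced)}
    (out / "prognosis_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


_STAGE_FUNCS = {
    "impute": _stage_impute,
    "diffexp": _stage_diffexp,
    "atlas": _stage_atlas,
    "cluster": _stage_cluster,
    "esi_corr": _stage_esi_corr,
    "screen": _stage_screen,
    "spia": _stage_spia,
    "prognosis": _stage_prognosis,
}
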