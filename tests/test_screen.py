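import numpy as np
import pandas as pd
import pytest

from ubipan.screen import classify_esi, run_screen, select_significant_e3
from ubipan.types import EnzymeCatalog, ESINetwork, ScreenThresholds, UbipanError


def de_row(log2fc, q):
    return pd.Series({"log2FC": log2fc, "q": q, "p": q / 2})


def site_rows(*stats):
    return pd.DataFrame([{"feature_id": f"SUB_K{i}", "log2FC": fc, "q": q}
                         for i, (fc, q) in enumerate(stats)])


class TestClassifyESI:
    def test_degradative_branch_one(self):
        # protein falls while mRNA holds: classic degradative signature
        call = classify_esi("E", "SUB", site_rows((0.3, 0.01)),
                            de_row(0.6, 0.001), de_row(-0.8, 0.005),
                            de_row(0.1, 0.4))
        assert call["call"] == "degradative"
        assert call["branch"] == "protein_down_mrna_not_down"
        assert call["evidence_sites"] == "SUB_K0"

    def test_failing_site_criterion_blocks_call(self):
        call = classify_esi("E", "SUB", site_rows((0.3, 0.2)),
                            de_row(0.6, 0.001), de_row(-0.8, 0.005),
                            de_row(0.1, 0.4))
        assert call["call"] == "none"

    def test_degradative_branch_two(self):
        # protein flat but mRNA surges: degradation masks transcription
        call = classify_esi("E", "SUB", site_rows((0.3, 0.01)),
                            de_row(0.6, 0.001), de_row(0.05, 0.5),
                            de_row(1.2, 0.001))
        assert call["call"] == "degradative"
        assert call["branch"] == "protein_flat_mrna_up"

    def test_over_ubiquitinated_without_degradation(self):
        call = classify_esi("E", "SUB", site_rows((0.3, 0.01)),
                            de_row(0.6, 0.001), de_row(0.4, 0.001),
                            de_row(0.1, 0.4))
        assert call["call"] == "over_ubiquitinated"
        assert call["branch"] == "none"

    def test_e3_fold_change_bound_is_inclusive(self):
        call = classify_esi("E", "SUB", site_rows((0.3, 0.01)),
                            de_row(0.5, 0.001), de_row(-0.8, 0.005),
                            de_row(0.1, 0.4))
        assert call["call"] == "degradative"

    def test_significantly_down_mrna_blocks_branch_one(self):
        call = classify_esi("E", "SUB", site_rows((0.3, 0.01)),
                            de_row(0.6, 0.001), de_row(-0.8, 0.005),
                            de_row(-1.0, 0.001))
        assert call["call"] == "over_ubiquitinated"

    def test_missing_layers_have_distinct_reason_codes(self):
        base = dict(site_rows_=site_rows((0.3, 0.01)),
                    e3=de_row(0.6, 0.001), prot=de_row(-0.8, 0.005),
                    rna=de_row(0.1, 0.4))
        combos = [
            (None, base["e3"], base["prot"], base["rna"], "no_site_data"),
            (base["site_rows_"], None, base["prot"], base["rna"],
             "no_e3_protein_data"),
            (base["site_rows_"], base["e3"], None, base["rna"],
             "no_substrate_protein_data"),
            (base["site_rows_"], base["e3"], base["prot"], None,
             "no_substrate_rna_data"),
        ]
        for sites, e3, prot, rna, reason in combos:
            call = classify_esi("E", "SUB", sites, e3, prot, rna)
            assert call["skip_reason"] == reason
            assert call["call"] == "none"


class TestSelectSignificantE3:
    def catalog(self):
        return EnzymeCatalog({"E1", "E2", "E3x"}, {"D1"})

    def test_boundary_fold_change_excluded(self):
        # |log2FC| strictly > 0.5 for "significant"; 0.5 exactly fails here
        # (though it satisfies screen criterion b, which is inclusive)
        de = pd.DataFrame({"feature_id": ["E1", "E2"],
                           "log2FC": [0.5, 0.8], "q": [0.001, 0.005]})
        out = select_significant_e3(de, self.catalog())
        assert out["up"] == ["E2"]

    def test_down_e3_split(self):
        de = pd.DataFrame({"feature_id": ["E1", "E2"],
                           "log2FC": [-0.9, 0.8], "q": [0.001, 0.005]})
        out = select_significant_e3(de, self.catalog())
        assert out == {"up": ["E2"], "down": ["E1"]}

    def test_empty_table(self):
        out = select_significant_e3(pd.DataFrame(columns=["feature_id",
                                                          "log2FC", "q"]),
                                    self.catalog())
        assert out == {"up": [], "down": []}


def run_small_screen(small_cohort, thresholds=None):
    from ubipan import diffexp, missing
    prot = missing.impute(missing.filter_missing(small_cohort["proteome"]))
    sites = missing.impute(missing.filter_missing(small_cohort["sites"]))
    prot_de = diffexp.test_differential(prot, paired=True)
    rna_de = diffexp.test_rna(small_cohort["rna"], paired=True)
    site_de = diffexp.test_sites(sites)
    return run_screen(small_cohort["esi"], site_de, prot_de, rna_de,
                      small_cohort["catalog"],
                      thresholds or ScreenThresholds()), (site_de, prot_de,
                                                          rna_de)


class TestRunScreen:
    def test_missing_layer_named_in_error(self, small_cohort):
        with pytest.raises(UbipanError, match="rna"):
            run_screen(small_cohort["esi"], pd.DataFrame({"a": [1]}),
                       pd.DataFrame({"a": [1]}), None,
                       small_cohort["catalog"])

    def test_empty_network_rejected(self, small_cohort):
        with pytest.raises(UbipanError, match="ESI"):
            run_screen(ESINetwork(set()), pd.DataFrame({"a": [1]}),
                       pd.DataFrame({"a": [1]}), pd.DataFrame({"a": [1]}),
                       small_cohort["catalog"])

    def test_degradative_nested_in_over_ubiquitinated(self, small_cohort):
        (table, summary), _ = run_small_screen(small_cohort)
        deg = table[table["call"] == "degradative"]
        over = table[table["call"].isin(["degradative", "over_ubiquitinated"])]
        assert set(map(tuple, deg[["e3", "substrate"]].values)) <= \
            set(map(tuple, over[["e3", "substrate"]].values))
        assert summary["degradative"]["n_pairs"] <= \
            summary["over_ubiquitinated"]["n_pairs"]

    def test_planted_pairs_recovered(self, small_cohort):
        (table, _), _ = run_small_screen(small_cohort)
        called = set(map(tuple,
                         table.loc[table["call"] == "degradative",
                                   ["e3", "substrate"]].values))
        truth = small_cohort["truth"].degradative_pairs
        assert len(called & truth) / len(truth) >= 0.8

    def test_tightening_thresholds_never_adds_calls(self, small_cohort):
        (loose_table, _), layers = run_small_screen(small_cohort)
        site_de, prot_de, rna_de = layers
        tight = ScreenThresholds(site_q_max=0.01, e3_q_max=0.005,
                                 prot_q_max=0.005, rna_q_max=0.005)
        tight_table, _ = run_screen(small_cohort["esi"], site_de, prot_de,
                                    rna_de, small_cohort["catalog"], tight)
        for call in ("degradative", "over_ubiquitinated"):
            loose_n = (loose_table["call"] == call).sum() if call != \
                "over_ubiquitinated" else loose_table["call"].isin(
                    ["degradative", "over_ubiquitinated"]).sum()
            tight_n = (tight_table["call"] == call).sum() if call != \
                "over_ubiquitinated" else tight_table["call"].isin(
                    ["degradative", "over_ubiquitinated"]).sum()
            assert tight_n <= loose_n

    def test_determinism(self, small_cohort):
        (a, _), _ = run_small_screen(small_cohort)
        (b, _), _ = run_small_screen(small_cohort)
        pd.testing.assert_frame_equal(a, b)
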