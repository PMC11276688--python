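import numpy as np
import pandas as pd
import pytest

from ubipan.prognosis import (
    bicor,
    cox_fit,
    group_diffexp,
    km_logrank,
    logrank_scores,
    maxstat_cutpoint,
    substrate_association,
)
from ubipan.simulate import simulate_survival
from ubipan.types import AbundanceMatrix, SurvivalTable, UbipanError

import oracles
from conftest import make_matrix


def survival_table(time, event, marker):
    return SurvivalTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(time))],
        "time": time, "event": event, "marker": marker}))


class TestCox:
    def test_sign_equivariance(self):
        surv = simulate_survival(100, 0.5, seed=0)
        a = cox_fit(surv)
        flipped = survival_table(surv.records["time"], surv.records["event"],
                                 -surv.records["marker"])
        b = cox_fit(flipped)
        assert b.beta == pytest.approx(-a.beta, abs=1e-6)

    def test_two_group_hazard_ratio_recovered(self):
        rng = np.random.default_rng(1)
        group = np.repeat([0.0, 1.0], 250)
        time = np.where(group == 1, rng.exponential(0.5, 500),
                        rng.exponential(1.0, 500))
        res = cox_fit(survival_table(time, np.ones(500, int), group))
        assert 1.7 <= res.hr <= 2.35

    def test_no_events_rejected(self):
        with pytest.raises(UbipanError):
            cox_fit(survival_table([1.0, 2.0, 3.0], [0, 0, 0], [1, 2, 3]))

    def test_constant_covariate_rejected(self):
        with pytest.raises(UbipanError):
            cox_fit(survival_table([1, 2, 3, 4], [1, 1, 1, 1], [2, 2, 2, 2]))


class TestMaxstat:
    def test_planted_threshold_recovered(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1, 150)
        time = np.where(m > 0.4, rng.exponential(10, 150),
                        rng.exponential(1, 150))
        surv = survival_table(time, np.ones(150, int), m)
        cut = maxstat_cutpoint(surv, n_perm=200, seed=3)
        below = m[m <= 0.4].max()
        above = m[m > 0.4].min()
        assert below - 0.15 <= cut.cutpoint <= above + 0.15
        assert cut.p < 0.05

    def test_group_sizes_respect_minimum(self):
        surv = simulate_survival(40, 0.8, seed=4)
        cut = maxstat_cutpoint(surv, min_group=5, n_perm=100, seed=5)
        assert cut.n_high >= 5 and cut.n_low >= 5

    def test_cutpoint_invariant_to_monotone_marker_transform(self):
        surv = simulate_survival(60, 0.8, seed=6)
        cut_raw = maxstat_cutpoint(surv, n_perm=50, seed=7)
        m = surv.records["marker"].to_numpy()
        transformed = survival_table(surv.records["time"],
                                     surv.records["event"], np.exp(m))
        cut_exp = maxstat_cutpoint(transformed, n_perm=50, seed=7)
        assert cut_exp.cutpoint == pytest.approx(np.exp(cut_raw.cutpoint))
        assert cut_exp.max_stat == pytest.approx(cut_raw.max_stat)
        assert cut_exp.p == cut_raw.p

    def test_same_seed_identical(self):
        surv = simulate_survival(50, 0.5, seed=8)
        a = maxstat_cutpoint(surv, n_perm=100, seed=9)
        b = maxstat_cutpoint(surv, n_perm=100, seed=9)
        assert (a.cutpoint, a.max_stat, a.p) == (b.cutpoint, b.max_stat, b.p)

    def test_constant_marker_rejected(self):
        with pytest.raises(UbipanError):
            maxstat_cutpoint(survival_table([1, 2, 3, 4], [1, 1, 1, 1],
                                            [1, 1, 1, 1]))

    def test_logrank_scores_sum_to_zero(self):
        surv = simulate_survival(30, 0.0, seed=10)
        scores = logrank_scores(surv.records["time"].to_numpy(),
                                surv.records["event"].to_numpy())
        # with no censoring the log-rank scores are exactly centered
        uncensored = simulate_survival(30, 0.0, censor_rate=0.0, seed=10)
        s = logrank_scores(uncensored.records["time"].to_numpy(),
                           uncensored.records["event"].to_numpy())
        assert abs(s.sum()) < 1e-10


class TestKMLogrank:
    def test_identical_groups_null(self):
        surv = simulate_survival(40, 0.5, seed=11)
        doubled = SurvivalTable(pd.concat([surv.records, surv.records])
                                .assign(sample_id=[f"s{i}" for i in range(80)]))
        chi2, p, curves = km_logrank(doubled, np.repeat([0, 1], 40))
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)
        assert set(curves) == {"0", "1"}

    def test_planted_hazard_difference_detected(self):
        rng = np.random.default_rng(12)
        group = np.repeat([0, 1], 100)
        time = np.where(group == 1, rng.exponential(1 / 3, 200),
                        rng.exponential(1.0, 200))
        surv = survival_table(time, np.ones(200, int), group)
        _, p, _ = km_logrank(surv, group)
        assert p < 0.01

    def test_agrees_with_cox_on_binary_covariate(self):
        rng = np.random.default_rng(13)
        agreements = 0
        for seed in range(10):
            surv = simulate_survival(80, 0.0, seed=seed)
            group = (surv.records["marker"] > 0).astype(int).to_numpy()
            surv.records["marker"] = group
            _, p_lr, _ = km_logrank(surv, group)
            p_cox = cox_fit(surv).p
            if p_lr < 1e-12 or p_cox < 1e-12:
                continue
            agreements += abs(np.log10(p_lr) - np.log10(p_cox)) < 1.0
        assert agreements >= 8

    def test_single_group_rejected(self):
        surv = simulate_survival(20, 0.5, seed=14)
        with pytest.raises(UbipanError):
            km_logrank(surv, np.zeros(20, int))


class TestBicor:
    def test_affine_relation_is_one(self):
        x = np.random.default_rng(15).normal(size=40)
        assert bicor(x, 2 * x + 1) == pytest.approx(1.0)

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(16).normal(size=30)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_matches_formula_replay(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            x = rng.normal(size=25)
            y = 0.6 * x + rng.normal(size=25)
            assert bicor(x, y) == pytest.approx(oracles.bicor_replay(x, y),
                                                abs=1e-12)

    def test_robust_to_gross_outlier(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=50)
        y = 0.9 * x + 0.1 * rng.normal(size=50)
        clean = np.corrcoef(x, y)[0, 1]
        y_out = y.copy()
        y_out[0] += 30.0
        pearson = np.corrcoef(x, y_out)[0, 1]
        assert abs(bicor(x, y_out) - clean) < abs(pearson - clean)

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.zeros(20)
        x[0] = 5.0  # median-absolute-deviation 0, but non-constant
        y = np.random.default_rng(19).normal(size=20)
        assert -1 <= bicor(x, y) <= 1

    def test_short_vectors_rejected(self):
        with pytest.raises(UbipanError):
            bicor(np.arange(5.0), np.arange(5.0))


class TestSubstrateAssociation:
    def build_proteome(self, rng, n_block=30, n_null=120):
        factor = rng.normal(size=60)
        block = (np.outer(np.ones(n_block), factor)
                 + 0.3 * rng.normal(size=(n_block, 60)))
        null = rng.normal(size=(n_null, 60))
        vals = np.vstack([factor, block, null])
        mat = make_matrix(vals)
        names = (["SUBSTRATE"] + [f"CO{i:03d}" for i in range(n_block)]
                 + [f"NU{i:03d}" for i in range(n_null)])
        mat.values.index = names
        return mat

    def test_self_excluded_and_block_ranked_top(self):
        mat = self.build_proteome(np.random.default_rng(20))
        table = substrate_association("SUBSTRATE", mat, top_n=50)
        assert "SUBSTRATE" not in set(table["symbol"])
        top50 = set(table["symbol"].head(50))
        assert all(f"CO{i:03d}" in top50 for i in range(30))

    def test_output_length_capped(self):
        mat = self.build_proteome(np.random.default_rng(21))
        table = substrate_association("SUBSTRATE", mat, top_n=10**6)
        assert len(table) == len(mat.feature_ids) - 1

    def test_absent_substrate_rejected(self):
        mat = self.build_proteome(np.random.default_rng(22))
        with pytest.raises(UbipanError):
            substrate_association("NOPE", mat)


class TestGroupDiffexp:
    def test_pronounced_threshold_is_inclusive(self):
        rng = np.random.default_rng(23)
        base = rng.normal(size=(40, 60)) * 0.1
        base[0, :30] += 2.0  # exactly log2FC 2 between groups in expectation
        mat = make_matrix(base, paired=False)
        high = np.array([True] * 30 + [False] * 30)
        table, sig, pronounced = group_diffexp(mat, high)
        row = table[table["feature_id"] == "F0000"].iloc[0]
        if row["q"] < 0.05 and abs(row["log2FC"]) >= 2.0:
            assert "F0000" in set(pronounced["feature_id"])

    def test_null_grouping_yields_no_discoveries(self):
        rng = np.random.default_rng(24)
        mat = make_matrix(rng.normal(size=(200, 40)), paired=False)
        high = np.array([True] * 20 + [False] * 20)
        _, sig, _ = group_diffexp(mat, high)
        assert len(sig) <= 2

    def test_delegates_to_rank_sum(self):
        from ubipan import diffexp as de_mod
        rng = np.random.default_rng(25)
        mat = make_matrix(rng.normal(size=(30, 20)), paired=False)
        high = np.array([True] * 10 + [False] * 10)
        table, _, _ = group_diffexp(mat, high)
        design = mat.design.copy()
        design["condition"] = np.where(high, "tumor", "normal")
        direct = de_mod.test_differential(
            AbundanceMatrix(mat.values.copy(), design), paired=False)
        pd.testing.assert_frame_equal(table, direct)

    def test_single_group_rejected(self):
        mat = make_matrix(np.random.default_rng(26).normal(size=(5, 10)),
                          paired=False)
        with pytest.raises(UbipanError):
            group_diffexp(mat, np.ones(10, bool))
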