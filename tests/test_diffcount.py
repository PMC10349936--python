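import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfredist import diffcount as dc
from tfredist import synthetic_data as syn

from conftest import make_count_matrix


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix([[5, 5], [9, 9]], ["DMSO", "dTAG"])
        assert np.allclose(dc.size_factors(cm), 1.0)

    def test_hand_computed_median_of_ratios(self):
        # counts [[2,4],[4,8]]: geomeans (sqrt(8), sqrt(32)); ratios
        # column1 (2/sqrt8, 4/sqrt32) = 1/sqrt2 each -> factor 1/sqrt2;
        # column2 -> sqrt2; geometric mean already 1
        cm = make_count_matrix([[2, 4], [4, 8]], ["DMSO", "dTAG"])
        sf = dc.size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 100, size=(40, 3))
        scaled = base.copy()
        scaled[:, 2] *= 3
        cm1 = make_count_matrix(base, ["DMSO", "dTAG", "dTAG"])
        cm2 = make_count_matrix(scaled, ["DMSO", "dTAG", "dTAG"])
        s1, s2 = dc.size_factors(cm1), dc.size_factors(cm2)
        # ratio of third factor to others triples (up to global rescale)
        assert np.isclose((s2.iloc[2] / s2.iloc[0]) / (s1.iloc[2] / s1.iloc[0]), 3.0)

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(1, 50, size=(30, 4))
        cm = make_count_matrix(arr, ["DMSO", "DMSO", "dTAG", "dTAG"])
        cm_perm = make_count_matrix(arr[::-1], ["DMSO", "DMSO", "dTAG", "dTAG"])
        assert np.allclose(dc.size_factors(cm), dc.size_factors(cm_perm))

    def test_error_when_no_all_positive_feature(self):
        cm = make_count_matrix([[0, 5], [5, 0]], ["DMSO", "dTAG"])
        with pytest.raises(ValueError, match="filter"):
            dc.size_factors(cm)


class TestDispersions:
    def test_variance_below_mean_floored(self):
        cm = make_count_matrix(
            [[10, 10, 10, 10]], ["DMSO", "DMSO", "DMSO", "DMSO"], [0, 0, 0, 0]
        )
        sf = pd.Series(1.0, index=cm.sample_ids)
        model = dc.estimate_dispersions(cm, sf)
        assert model.raw.iloc[0] == model.floor

    def test_poisson_data_small_dispersion(self):
        rng = np.random.default_rng(2)
        arr = rng.poisson(300, size=(400, 8))
        cm = make_count_matrix(arr, ["DMSO"] * 4 + ["dTAG"] * 4, [0] * 4 + [30] * 4)
        sf = dc.size_factors(cm)
        model = dc.estimate_dispersions(cm, sf)
        assert model.shrunk.median() < 0.01

    def test_planted_dispersion_recovered(self):
        n = 1000
        truth = syn.TruthTable.from_planted_lfc(
            [f"f{i}" for i in range(n)], (0, 30), np.zeros((n, 2)), seed=11
        )
        cfg = syn.SimulationConfig(seed=11, dispersion=0.1)
        cm = syn.simulate_timecourse_counts(truth, cfg, timepoints=(0, 30))
        sf = dc.size_factors(cm)
        model = dc.estimate_dispersions(cm, sf)
        assert 0.05 <= model.shrunk.median() <= 0.2


class TestWald:
    def test_no_effect_identity(self):
        arr = np.array([[10, 17, 10, 17], [40, 3, 40, 3]])
        cm = make_count_matrix(arr, ["DMSO", "DMSO", "dTAG", "dTAG"], [0, 0, 30, 30])
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = dc.estimate_dispersions(cm, sf)
        res = dc.wald_test(cm, sf, disp, ("dTAG", "DMSO"))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)

    def test_two_group_closed_form(self):
        """Saturated two-group NB GLM: fitted group means are arithmetic
        means, so log2fc = log2(40/10) = 2 exactly."""
        cm = make_count_matrix([[10, 10, 40, 40]], ["DMSO", "DMSO", "dTAG", "dTAG"], [0, 0, 30, 30])
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = dc.estimate_dispersions(cm, sf)
        res = dc.wald_test(cm, sf, disp, ("dTAG", "DMSO"))
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_all_zero_feature_gets_na(self):
        cm = make_count_matrix(
            [[0, 0, 0, 0], [5, 6, 7, 8]], ["DMSO", "DMSO", "dTAG", "dTAG"], [0, 0, 30, 30]
        )
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = dc.estimate_dispersions(cm, sf)
        res = dc.wald_test(cm, sf, disp, ("dTAG", "DMSO"))
        assert np.isnan(res["pvalue"].iloc[0]) and not np.isnan(res["pvalue"].iloc[1])

    def test_planted_lfc_recovered(self, two_group_counts):
        cm, truth = two_group_counts
        res = dc.differential_analysis(cm, contrast=("dTAG", "DMSO"))
        merged = res.set_index("feature_id").join(truth.features, rsuffix="_true")
        est = merged.loc[merged["lfc_t30"] == 2.0, "log2fc"]
        assert abs(est.mean() - 2.0) < 0.2


class TestLRT:
    def test_two_timepoints_df_one_matches_wald_path(self):
        arr = np.array([[12, 9, 30, 41], [100, 90, 95, 105]])
        cm = make_count_matrix(arr, ["DMSO", "DMSO", "dTAG", "dTAG"], [0, 0, 30, 30])
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = dc.estimate_dispersions(cm, sf)
        res = dc.lrt_timecourse(cm, sf, disp)
        # df = 1; the LRT statistic equals the deviance difference of the
        # same nested NB GLMs computed independently
        import statsmodels.api as sm

        y = arr[0].astype(float)
        fam = sm.families.NegativeBinomial(alpha=disp.alpha(cm.feature_ids[0]))
        X_full = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        full = sm.GLM(y, X_full, family=fam).fit()
        red = sm.GLM(y, np.ones((4, 1)), family=fam).fit()
        expected = 2 * (full.llf - red.llf)
        assert res["stat"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_power_on_monotone_trajectory(self):
        """Dynamic features with a monotone 0 -> 2 log2FC trajectory are
        detected by the time-course LRT at FDR 0.1 with power >= 0.8."""
        n_dyn, n_null = 150, 350
        tps = (0, 30, 60, 120)
        ramp = np.array([0.0, 0.7, 1.4, 2.0])
        lfc = np.vstack([np.tile(ramp, (n_dyn, 1)), np.zeros((n_null, len(tps)))])
        ids = [f"f{i}" for i in range(n_dyn + n_null)]
        truth = syn.TruthTable.from_planted_lfc(ids, tps, lfc, seed=13)
        cfg = syn.SimulationConfig(seed=13, dispersion=0.05)
        cm = syn.simulate_timecourse_counts(truth, cfg, timepoints=tps)
        res = dc.differential_analysis(cm, test="lrt")
        power = (res.set_index("feature_id").loc[ids[:n_dyn], "padj"] < 0.1).mean()
        assert power >= 0.8


class TestShrink:
    def test_zero_se_limit_no_shrinkage(self):
        df = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "log2fc": [2.0, -1.0, 0.5],
                "log2fc_se": [1e-9, 1.0, 1.0],
            }
        )
        out = dc.shrink_lfc(df)
        assert out["shrunken_log2fc"].iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_all_zero_lfc_all_zero_shrunken(self):
        df = pd.DataFrame(
            {"feature_id": list("abc"), "log2fc": [0.0] * 3, "log2fc_se": [1.0] * 3}
        )
        assert (dc.shrink_lfc(df)["shrunken_log2fc"] == 0).all()

    def test_stated_formula_halves_at_equal_variance(self):
        # build data where var(lfc) - mean(se^2) = tau2 = se^2 exactly
        rng = np.random.default_rng(3)
        se = 1.0
        lfc = rng.normal(0, np.sqrt(2), 4000)  # var = tau2 + se2 = 2
        df = pd.DataFrame(
            {"feature_id": np.arange(4000), "log2fc": lfc, "log2fc_se": se}
        )
        out = dc.shrink_lfc(df)
        ratio = out["shrunken_log2fc"] / out["log2fc"]
        assert abs(ratio.mean() - 0.5) < 0.05


class TestBH:
    def test_hand_computed_example(self):
        q = dc.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_identity(self):
        assert dc.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_capped(self):
        assert (dc.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dc.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, ps):
        """Property: the implementation equals the step-up definition
        q_(i) = min over j >= i of min(1, m p_(j) / j)."""
        q = dc.bh_adjust(ps)
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, min(1.0, m * p[idx] / rank))
            brute[idx] = running
        assert np.allclose(q, brute, atol=1e-12)


class TestClassify:
    def test_fdr_rule(self):
        df = pd.DataFrame(
            {
                "feature_id": list("abcd"),
                "log2fc": [1.0, -1.0, 0.0, 2.0],
                "padj": [0.05, 0.05, 0.05, np.nan],
            }
        )
        out = dc.classify_features(df, fdr=0.1)
        assert list(out["class"]) == ["increased", "decreased", "unchanged", "unchanged"]

    def test_partition_is_exhaustive(self, two_group_counts):
        cm, _ = two_group_counts
        res = dc.differential_analysis(cm, contrast=("dTAG", "DMSO"))
        counts = res["class"].value_counts()
        assert counts.sum() == len(res)
        assert set(counts.index) <= {"increased", "decreased", "unchanged"}
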