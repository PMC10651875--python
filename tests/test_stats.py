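"""Statistical battery: gates, paired tests, Holm, regressions, clinical."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from slowspec import stats as st


class TestShapiroGate:
    def test_normal_diffs_mostly_t(self, rng):
        picks = [st.shapiro_gate(rng.normal(0, 1, 22)) for _ in range(200)]
        frac_t = np.mean([p == "paired_t" for p in picks])
        assert 0.90 <= frac_t <= 0.99  # gate at alpha = 0.05

    def test_lognormal_diffs_mostly_wilcoxon(self, rng):
        picks = [st.shapiro_gate(rng.lognormal(0, 1, 22)) for _ in range(100)]
        assert np.mean([p == "wilcoxon" for p in picks]) > 0.5

    def test_too_few_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            st.shapiro_gate(np.array([1.0, 2.0]))

    def test_constant_diffs_fall_back_to_wilcoxon(self):
        with pytest.warns(UserWarning, match="constant"):
            assert st.shapiro_gate(np.ones(10)) == "wilcoxon"


class TestPairedTest:
    def test_identical_samples_degenerate(self):
        x = np.arange(10, dtype=float)
        res = st.paired_test(x, x, choice="paired_t")
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.effect == 0.0

    def test_clear_separation(self, rng):
        pre = rng.normal(0, 0.01, 12)
        post = pre - 1.0 + rng.normal(0, 0.01, 12)
        res = st.paired_test(pre, post, choice="paired_t")
        assert res.p < 1e-3
        assert res.effect > 5  # d_z on pre-minus-post ~ +1/0.01

    def test_wilcoxon_branch_descriptives(self, rng):
        pre, post = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        res = st.paired_test(pre, post, choice="wilcoxon")
        assert res.test == "wilcoxon"
        assert res.effect_type == "cliffs_delta"
        assert "pre_median" in res.descriptives
        assert -1 <= res.effect <= 1

    def test_statistic_is_smaller_rank_sum(self):
        # hand case: diffs ranks -> W+ = 2, W- = 13, W = 2
        pre = np.array([3.0, 5.0, 7.0, 9.0, 11.0])
        post = np.array([4.0, 3.0, 4.0, 5.0, 6.0])
        res = st.paired_test(pre, post, choice="wilcoxon")
        assert res.statistic == 1.0  # only the -1 diff is negative, rank 1

    def test_exact_p_matches_enumeration(self):
        from slowspec.validation import wilcoxon_enumeration_check

        assert wilcoxon_enumeration_check(50, seed=2)["max_abs_p_diff"] == 0.0

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.3, 1, 40)
        w, p, n = st.wilcoxon_signed_rank(d)
        from scipy.stats import wilcoxon

        ref = wilcoxon(d, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestCliffsDelta:
    def test_identical_zero(self):
        x = np.arange(5, dtype=float)
        assert st.cliffs_delta(x, x) == 0.0

    def test_bounds(self):
        assert st.cliffs_delta([4.0, 5.0], [1.0, 2.0]) == 1.0
        assert st.cliffs_delta([1.0, 2.0], [4.0, 5.0]) == -1.0

    def test_matches_brute_force(self):
        from slowspec.validation import cliffs_delta_brute_force_check

        assert cliffs_delta_brute_force_check(200, seed=3)["max_abs_diff"] == 0.0


class TestHolm:
    PRINTED_M8 = [0.00625, 0.00714, 0.00833, 0.01, 0.0125, 0.0167, 0.025, 0.05]

    def test_printed_threshold_ladder(self):
        res = st.holm_bonferroni(np.linspace(1e-4, 1e-3, 8))
        for got, want in zip(res.table["threshold"], self.PRINTED_M8):
            assert got == pytest.approx(want, rel=5e-3)

    def test_single_test_threshold(self):
        res = st.holm_bonferroni([0.03])
        assert res.table["threshold"].iloc[0] == 0.05
        assert res.table["reject"].iloc[0]

    def test_three_effect_family_rank1(self):
        res = st.holm_bonferroni([0.001, 0.2, 0.3])
        assert res.table["threshold"].iloc[0] == pytest.approx(0.0167, rel=5e-3)

    def test_step_down_stops_at_first_failure(self):
        # rank 1: 0.03 > 0.025 fails, so rank 2 (0.04 <= 0.05) is blocked
        res = st.holm_bonferroni([0.03, 0.04], ["a", "b"])
        tbl = res.table.set_index("label")
        assert not tbl["reject"].any()
        assert bool(tbl.loc["b", "below_threshold"])  # per-rank view differs
        # all-pass family: every step succeeds
        res2 = st.holm_bonferroni([0.001, 0.03, 0.002], ["a", "b", "c"])
        assert res2.table["reject"].all()

    def test_rejection_set_is_prefix(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 0.2, 8)
            rej = st.holm_bonferroni(p).table["reject"].to_numpy()
            if (~rej).any():
                first_accept = np.argmin(rej)
                assert not rej[first_accept:].any()

    @given(
        pvals=hst.lists(hst.floats(0.0, 1.0), min_size=2, max_size=10),
        idx=hst.integers(0, 9),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_lowering_a_p_never_shrinks_rejections(self, pvals, idx):
        idx = idx % len(pvals)
        before = int(st.holm_bonferroni(pvals).table["reject"].sum())
        lowered = list(pvals)
        lowered[idx] = lowered[idx] / 2.0
        after = int(st.holm_bonferroni(lowered).table["reject"].sum())
        assert after >= before

    def test_tie_resolved_by_declared_order(self):
        res = st.holm_bonferroni([0.02, 0.001, 0.02], ["x", "y", "z"])
        assert list(res.table["label"]) == ["y", "x", "z"]


class TestClinical:
    def test_normalize_endpoints_and_versions(self):
        assert st.normalize_hamd(0, 17) == 0.0
        assert st.normalize_hamd(52, 17) == 1.0
        assert st.normalize_hamd(38, 24) == pytest.approx(0.5)
        assert st.normalize_hamd(26, 17) == pytest.approx(0.5)

    def test_normalize_monotone(self):
        vals = [st.normalize_hamd(r, 24) for r in range(0, 77, 4)]
        assert np.all(np.diff(vals) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            st.normalize_hamd(60, 17)
        with pytest.raises(ValueError, match="version"):
            st.normalize_hamd(10, 21)

    def test_remission_rule(self):
        assert st.remission_rate([20, 18], [0, 0]) == 100.0
        assert st.remission_rate([20, 18], [20, 18]) == 0.0
        # exactly half counts ("equal or larger than 50% decrease")
        assert st.remission_rate([20, 20, 20, 20], [10, 11, 9, 20]) == 50.0

    def test_zero_baseline_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="baseline 0"):
            assert st.remission_rate([0, 20], [0, 5]) == 100.0


class TestHC3:
    def test_hand_worked_sandwich(self):
        from slowspec.validation import hc3_hand_check

        assert hc3_hand_check()["max_abs_se_diff"] < 1e-10

    def test_homoskedastic_close_to_classical(self, rng):
        n = 100
        x = rng.normal(0, 1, n)
        y = 2 + 0.5 * x + rng.normal(0, 1, n)
        hc3 = st.hc3_ols(y, pd.DataFrame({"x": x}))
        ols = st.hc3_ols(y, pd.DataFrame({"x": x}), cov_type="standard")
        ratio = hc3.bse["x"] / ols.bse["x"]
        assert 0.8 < ratio < 1.2

    def test_duplicate_predictor_rank_error(self, rng):
        x = rng.normal(0, 1, 20)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="rank"):
            st.hc3_ols(rng.normal(0, 1, 20), X)

    def test_ci_contains_beta(self, rng):
        x = rng.normal(0, 1, 30)
        y = 1 + x + rng.normal(0, 0.5, 30)
        res = st.hc3_ols(y, pd.DataFrame({"x": x}))
        assert res.conf_int.loc["x", "lower"] < res.params["x"] < res.conf_int.loc["x", "upper"]
        assert res.r_squared_adj <= res.r_squared


class TestBandPowerRegression:
    def _features(self, rng, n=20, beta=0.9):
        exp_d = rng.normal(0, 1, n)
        ab_d = rng.normal(0, 1, n)
        osc_d = rng.normal(0, 1, n)
        bp_d = beta * exp_d + rng.normal(0, np.sqrt(max(1 - beta**2, 1e-6)), n)
        return pd.DataFrame(
            {
                "delta_power_diff": bp_d,
                "exponent_diff": exp_d,
                "delta_abundance_diff": ab_d,
                "delta_osc_diff": osc_d,
            }
        )

    def test_planted_exponent_effect_recovered(self, rng):
        betas = []
        for _ in range(50):
            reg, _holm = st.band_power_regression(self._features(rng), "delta")
            betas.append(reg.params["exponent_diff"])
        assert np.mean(betas) == pytest.approx(0.9, abs=0.05)

    def test_null_overall_f_calibrated(self, rng):
        sig = 0
        reps = 200
        for _ in range(reps):
            df = self._features(rng, beta=0.0)
            df["delta_power_diff"] = rng.normal(0, 1, len(df))
            reg, _ = st.band_power_regression(df, "delta")
            sig += reg.f_pvalue < 0.05
        assert sig / reps == pytest.approx(0.05, abs=0.04)

    def test_standardized_beta_scale_invariant(self, rng):
        df = self._features(rng)
        reg1, _ = st.band_power_regression(df, "delta")
        df2 = df.copy()
        df2["exponent_diff"] = df2["exponent_diff"] * 1000 + 5
        reg2, _ = st.band_power_regression(df2, "delta")
        assert reg1.params["exponent_diff"] == pytest.approx(
            reg2.params["exponent_diff"], abs=1e-9
        )

    def test_duplicate_predictor_rejected(self, rng):
        df = self._features(rng)
        df["delta_osc_diff"] = df["exponent_diff"]
        with pytest.raises(ValueError, match="rank"):
            st.band_power_regression(df, "delta")

    def test_too_few_cases_rejected(self, rng):
        df = self._features(rng, n=4)
        with pytest.raises(ValueError, match="complete cases"):
            st.band_power_regression(df, "delta")

    def test_holm_family_of_three(self, rng):
        _reg, holm = st.band_power_regression(self._features(rng), "delta")
        assert holm.table["threshold"].iloc[0] == pytest.approx(0.0167, rel=5e-3)
        assert len(holm.table) == 3


class TestOutcomeSearch:
    def test_single_candidate_degenerate(self, rng):
        n = 20
        df = pd.DataFrame(
            {
                "norm_hamd_post": rng.uniform(0, 1, n),
                "norm_hamd_pre": rng.uniform(0.3, 0.8, n),
                "treatment_code": rng.integers(0, 2, n).astype(float),
                "exponent_pre": rng.normal(1, 0.2, n),
            }
        )
        sel, reg = st.exhaustive_outcome_search(df, candidates=["exponent_pre"])
        assert sel == ("exponent_pre",)
        assert reg.cov_type == "HC3"
        assert "norm_hamd_pre" in reg.params.index
        assert "treatment_code" in reg.params.index

    def test_planted_model_recovered(self):
        from slowspec.validation import planted_selection_rate

        assert planted_selection_rate(n_reps=20, seed=5)["fraction"] >= 0.8


class TestTopography:
    def _frames(self, rng, n_pat=22, n_el=8, shift=0.0):
        pre = pd.DataFrame(
            rng.normal(1.0, 0.2, (n_pat, n_el)), columns=[f"e{i}" for i in range(n_el)]
        )
        noise = pd.DataFrame(
            rng.normal(0, 0.05, (n_pat, n_el)), columns=pre.columns
        )
        return pre, pre + shift + noise

    def test_uniform_shift_all_significant(self, rng):
        pre, post = self._frames(rng, shift=0.35)
        res = st.electrode_topography_tests(pre, post)
        assert (res["p"] < 0.05).all()
        assert (res["median_diff"] < 0).all()  # pre minus post

    def test_null_calibrated(self, rng):
        hits, total = 0, 0
        for _ in range(25):
            pre, post = self._frames(rng, shift=0.0)
            res = st.electrode_topography_tests(pre, post)
            hits += int((res["p"] < 0.05).sum())
            total += len(res)
        assert hits / total == pytest.approx(0.05, abs=0.04)

    def test_mostly_missing_electrode_flagged(self, rng):
        pre, post = self._frames(rng, n_pat=10, shift=0.3)
        pre.loc[pre.index[:6], "e0"] = np.nan
        res = st.electrode_topography_tests(pre, post).set_index("electrode")
        assert bool(res.loc["e0", "flagged"])
        assert not bool(res.loc["e1", "flagged"])

    def test_too_few_patients_rejected(self, rng):
        pre, post = self._frames(rng, n_pat=2)
        with pytest.raises(ValueError, match="3 patients"):
            st.electrode_topography_tests(pre, post)
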