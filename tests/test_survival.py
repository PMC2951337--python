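import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from lumisig.survival import (
    death_count_chisq,
    doubling_time,
    expression_group_tests,
    km_estimate,
    logrank_test,
    pcr_chisq,
    rank_split,
)
from lumisig.synthdata import CohortSimSpec, simulate_cohort


class TestRankSplit:
    def test_even_n_hand_example(self):
        s = rank_split(pd.Series([4.0, 3.0, 2.0, 1.0], index=list("wxyz")))
        assert s.tolist() == ["high", "high", "low", "low"]

    def test_odd_n_high_gets_ceiling(self):
        s = rank_split(pd.Series([5.0, 4.0, 3.0, 2.0, 1.0]))
        assert (s == "high").sum() == 3

    def test_all_tied_stable_order(self):
        s = rank_split(pd.Series([1.0] * 5, index=list("abcde")))
        assert s[list("abc")].tolist() == ["high"] * 3
        assert s[list("de")].tolist() == ["low"] * 2

    def test_group_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 10, 47):
            s = rank_split(pd.Series(rng.normal(size=n)))
            counts = s.value_counts()
            assert abs(counts.get("high", 0) - counts.get("low", 0)) <= 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_split(pd.Series([np.nan, np.nan]))


class TestKmEstimate:
    def test_no_events_flat_curve(self):
        curves = km_estimate([5.0, 6.0, 7.0], [False, False, False])
        c = curves["all"]
        assert len(c.times) == 0  # no steps at all

    def test_hand_product_limit(self):
        curves = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        c = curves["all"]
        assert np.allclose(c.times, [1.0, 2.0, 3.0])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(c.at_risk, [3, 2, 1])

    def test_censoring_reduces_at_risk_without_step(self):
        curves = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        c = curves["all"]
        assert np.allclose(c.times, [1.0, 3.0])
        assert np.allclose(c.survival, [2 / 3, 0.0])

    def test_time_scale_equivariance(self):
        t = np.array([1.0, 2.0, 4.0, 8.0])
        e = np.array([True, True, False, True])
        a = km_estimate(t, e)["all"]
        b = km_estimate(2 * t, e)["all"]
        assert np.allclose(b.times, 2 * a.times)
        assert np.allclose(b.survival, a.survival)

    def test_curve_monotone_within_unit_interval(self):
        _, clin = simulate_cohort(
            CohortSimSpec(n_per_subtype=20, censor_rate=0.3, seed=1)
        )
        c = km_estimate(clin["os_time"], clin["os_event"])["all"]
        assert (np.diff(c.survival) <= 1e-12).all()
        assert (c.survival >= 0).all() and (c.survival <= 1).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.ones(6, dtype=bool)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = logrank_test(t, e, g)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.7
        g = np.array(["a"] * 40 + ["b"] * 40)
        mine = logrank_test(t, e, g)
        ref = ll_logrank(t[:40], t[40:], e[:40], e[40:])
        assert mine["chi2"] == pytest.approx(ref.test_statistic, rel=1e-10)
        assert mine["p"] == pytest.approx(ref.p_value, rel=1e-10)

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 60)
        e = rng.random(60) < 0.8
        g = np.array(["a"] * 30 + ["b"] * 30)
        assert logrank_test(t, e, g)["chi2"] == pytest.approx(
            logrank_test(np.sqrt(t), e, g)["chi2"]
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [True, True], ["a", "a"])

    def test_death_count_variant_runs(self):
        e = np.array([True, False, True, True, False, False])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = death_count_chisq(e, g)
        assert res["df"] == 1 and 0 <= res["p"] <= 1


class TestGroupTests:
    def test_identical_two_groups(self):
        x = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = expression_group_tests(x, ["a"] * 3 + ["b"] * 3)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=20))
        g2 = ["a"] * 10 + ["b"] * 10
        t_res = expression_group_tests(x, g2)
        # same data as a 2-level one-way layout via scipy ANOVA
        from scipy.stats import f_oneway

        f_stat, _ = f_oneway(x[:10], x[10:])
        assert t_res["statistic"] ** 2 == pytest.approx(f_stat, abs=1e-10)

    def test_planted_subtype_shift_detected(self):
        m, clin = simulate_cohort(CohortSimSpec(n_per_subtype=15, seed=5))
        res = expression_group_tests(m.loc["MYB"], clin["subtype"])
        assert res["test"] == "anova" and res["p"] < 0.01


class TestPcrChisq:
    def test_proportional_table_zero(self):
        res = pcr_chisq(np.array([[10, 10], [20, 20]]))
        assert res["chi2"] == pytest.approx(0.0)

    def test_hand_computed_observed_expected(self):
        # margins 30/30 x 30/30, E = 15 everywhere: chi2 = 4*25/15
        res = pcr_chisq(np.array([[10, 20], [20, 10]]))
        assert res["chi2"] == pytest.approx(20 / 3, abs=1e-12)

    def test_transpose_symmetry(self):
        t = np.array([[3, 11], [7, 2]])
        assert pcr_chisq(t)["chi2"] == pytest.approx(pcr_chisq(t.T)["chi2"])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pcr_chisq(np.array([[0, 0], [5, 5]]))


class TestDoublingTime:
    def test_exact_doubling_every_24h(self):
        times = np.array([0.0, 24.0, 48.0, 72.0])
        counts = 1000 * 2 ** (times / 24.0)
        assert doubling_time(counts, times) == pytest.approx(24.0)

    def test_quadrupling_over_48h(self):
        assert doubling_time([1000, 2000, 4000], [0.0, 24.0, 48.0]) == (
            pytest.approx(24.0)
        )

    def test_noisy_exponential_mean_within_two_percent(self):
        rng = np.random.default_rng(6)
        times = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
        ests = []
        for _ in range(1000):
            counts = 1000 * 2 ** (times / 24.0) * np.exp(
                rng.normal(0, 0.05, size=len(times))
            )
            ests.append(doubling_time(counts, times))
        assert abs(np.mean(ests) - 24.0) / 24.0 < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            doubling_time([100, 50, 25], [0.0, 24.0, 48.0])  # shrinking
        with pytest.raises(ValueError):
            doubling_time([100, -5, 25], [0.0, 24.0, 48.0])
        with pytest.raises(ValueError):
            doubling_time([100, 200], [0.0, 24.0])
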