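"""Attrition accounting, power loss, ATE estimation, and balance tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialbounds import (
    TrialDataset,
    attrition_rates,
    balance_test,
    estimate_ate,
    mcar_mar_comparison,
    monotonicity_check,
    power_after_attrition,
)
from trialbounds.data import DegenerateDesignError
from trialbounds.diagnostics import CollinearityError

from conftest import make_trial


def _attrition_pattern(n_treated, obs_treated, n_control, obs_control):
    y = np.concatenate(
        [
            np.r_[np.random.default_rng(0).normal(size=obs_treated),
                  np.full(n_treated - obs_treated, np.nan)],
            np.r_[np.random.default_rng(1).normal(size=obs_control),
                  np.full(n_control - obs_control, np.nan)],
        ]
    )
    t = np.r_[np.ones(n_treated, int), np.zeros(n_control, int)]
    return TrialDataset.from_arrays(y, t)


class TestAttritionRates:
    def test_acrophobia_trial_counts_give_34_percent(self):
        ds = _attrition_pattern(96, 56, 97, 86)
        att = attrition_rates(ds)
        assert att.q_control == pytest.approx(86 / 97)
        assert att.q_treated == pytest.approx(56 / 96)
        assert att.trim_share == pytest.approx(0.34, abs=0.005)
        assert att.trimmed_arm == "control"
        assert att.n_fs == 193 and att.n_os == 142

    def test_equal_rates_give_zero_trim(self):
        ds = _attrition_pattern(10, 8, 10, 8)
        assert attrition_rates(ds).trim_share == 0.0

    def test_half_rate_differential(self):
        ds = _attrition_pattern(4, 2, 4, 4)
        att = attrition_rates(ds)
        assert att.q_control == 1.0
        assert att.q_treated == 0.5
        assert att.trim_share == 0.5

    def test_row_permutation_invariance(self):
        ds = _attrition_pattern(30, 20, 25, 24)
        perm = np.random.default_rng(3).permutation(ds.n)
        shuffled = TrialDataset(
            ds.frame.iloc[perm].reset_index(drop=True), ds.covariates
        )
        assert attrition_rates(shuffled) == attrition_rates(ds)

    def test_zero_observed_arm_is_degenerate(self):
        y = np.array([np.nan, np.nan, 1.0, 2.0])
        with pytest.raises(DegenerateDesignError):
            attrition_rates(TrialDataset.from_arrays(y, [1, 1, 0, 0]))


class TestPowerLoss:
    def test_full_sample_recovers_80_percent_power(self):
        res = power_after_attrition(100, 100)
        assert res.theta == pytest.approx(0.84)
        assert res.power == pytest.approx(0.80, abs=0.005)

    def test_quarter_attrition_drops_power_to_56_percent(self):
        res = power_after_attrition(75, 100)
        assert res.theta == pytest.approx(0.14)
        assert round(res.power, 2) == 0.56

    def test_ratio_09_normal_cdf(self):
        res = power_after_attrition(90, 100)
        assert res.theta == pytest.approx(0.56)
        assert res.power == pytest.approx(stats.norm.cdf(0.56))
        assert res.power == pytest.approx(0.712, abs=0.001)

    def test_power_strictly_increasing_in_ratio(self):
        powers = [power_after_attrition(k, 100).power for k in range(10, 101, 5)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_theta_linear_in_ratio_with_slope_28(self):
        t1 = power_after_attrition(50, 100).theta
        t2 = power_after_attrition(60, 100).theta
        assert (t2 - t1) / 0.1 == pytest.approx(2.8)

    def test_sqrt_mode_agrees_at_full_sample_only(self):
        assert power_after_attrition(100, 100, mode="sqrt").theta == pytest.approx(0.84)
        assert power_after_attrition(75, 100, mode="sqrt").theta == pytest.approx(
            2.8 * np.sqrt(0.75) - 1.96
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            power_after_attrition(101, 100)
        with pytest.raises(ValueError):
            power_after_attrition(0, 100)


class TestEstimateAte:
    def test_unadjusted_equals_mean_difference(self):
        ds = TrialDataset.from_arrays([1.0, 3.0, 0.0, 2.0], [1, 1, 0, 0])
        res = estimate_ate(ds)
        assert res.beta == pytest.approx(1.0)

    def test_unadjusted_matches_arm_means_to_1e10(self):
        rng = np.random.default_rng(11)
        ds = make_trial(rng, mean_treated=3.2, mean_control=1.1)
        res = estimate_ate(ds)
        diff = ds.observed_outcomes(1).mean() - ds.observed_outcomes(0).mean()
        assert res.beta == pytest.approx(diff, rel=1e-10)

    def test_adjusted_matches_normal_equations_on_six_points(self):
        # closed-form OLS on 6 points with one binary covariate
        y = np.array([2.0, 4.0, 6.0, 1.0, 3.0, 2.0])
        t = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        ds = TrialDataset.from_arrays(y, t, covariates={"x": x})
        X = np.column_stack([np.ones(6), t, x])
        beta_hand = np.linalg.solve(X.T @ X, X.T @ y)
        res = estimate_ate(ds, adjusted=True)
        assert res.beta == pytest.approx(beta_hand[1], rel=1e-10)
        assert res.covariate_coefficients.loc["x", "coef"] == pytest.approx(
            beta_hand[2], rel=1e-10
        )

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        ds = TrialDataset.from_arrays(
            rng.normal(size=20), [1] * 10 + [0] * 10,
            covariates={"x1": x, "x2": 2 * x},
        )
        with pytest.raises(CollinearityError, match="x1|x2"):
            estimate_ate(ds, adjusted=True)

    def test_requires_two_observed_per_arm(self):
        y = np.array([1.0, np.nan, np.nan, 2.0, 3.0, 4.0])
        ds = TrialDataset.from_arrays(y, [1, 1, 1, 0, 0, 0])
        with pytest.raises(DegenerateDesignError):
            estimate_ate(ds)


class TestBalanceTest:
    def test_perfectly_balanced_covariate(self):
        x = np.tile([1.0, 2.0, 3.0], 4)
        t = np.r_[np.ones(6, int), np.zeros(6, int)]
        ds = TrialDataset.from_arrays(np.ones(12), t, covariates={"x": x})
        res = balance_test(ds, "full")
        assert abs(res.coefficients["coef"]).max() < 1e-10
        assert res.p_value > 0.99

    def test_perfect_prediction_flags_imbalance(self):
        t = np.r_[np.ones(10, int), np.zeros(10, int)]
        ds = TrialDataset.from_arrays(
            np.ones(20), t, covariates={"x": t.astype(float)}
        )
        res = balance_test(ds, "full")
        assert res.p_value < 1e-6

    def test_constant_covariate_dropped_with_reduced_df(self):
        rng = np.random.default_rng(5)
        t = np.r_[np.ones(15, int), np.zeros(15, int)]
        ds = TrialDataset.from_arrays(
            rng.normal(size=30), t,
            covariates={"konst": np.ones(30), "x": rng.normal(size=30)},
        )
        res = balance_test(ds, "full")
        assert res.dropped_covariates == ("konst",)
        assert res.df == 1

    def test_type_i_error_within_binomial_band(self):
        # 1,000 randomized trials with X independent of T at alpha = 0.05:
        # the rejection fraction must stay inside the 99% binomial band
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            t = np.r_[np.ones(30, int), np.zeros(30, int)]
            x = rng.normal(size=60)
            ds = TrialDataset.from_arrays(rng.normal(size=60), t, covariates={"x": x})
            rejections += balance_test(ds, "full").p_value < 0.05
        band = 2.576 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rejections / n_reps - 0.05) < band + 0.01

    def test_trimmed_sample_requires_rows(self):
        ds = TrialDataset.from_arrays(
            [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], covariates={"x": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="trimmed_rows"):
            balance_test(ds, "trimmed")


class TestMcarMarComparison:
    def test_orthogonal_covariate_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(21)
        n = 200
        t = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        x = np.tile([0.0, 1.0], n // 2)  # exactly balanced, outcome-unrelated
        y = 1.5 * t + rng.normal(size=n)
        ds = TrialDataset.from_arrays(y, t, covariates={"x": x})
        res = mcar_mar_comparison(ds, n_bootstrap=100, seed=1)
        assert abs(res.difference) < 0.05
        assert abs(res.z_value) < 2

    def test_outcome_related_covariate_with_selective_attrition_shifts_beta(self):
        rng = np.random.default_rng(22)
        n = 400
        t = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        x = rng.normal(size=n)
        y = 2.0 * t + 3.0 * x + rng.normal(size=n)
        # attrition depends on x in the treated arm only
        s = np.where(t == 1, x > -0.2, np.ones(n, bool))
        ds = TrialDataset.from_arrays(np.where(s, y, np.nan), t, covariates={"x": x})
        res = mcar_mar_comparison(ds, n_bootstrap=100, seed=2)
        assert abs(res.z_value) > 2


class TestMonotonicityCheck:
    def test_no_trimming_equals_observed_only_balance(self):
        rng = np.random.default_rng(31)
        ds = make_trial(rng, obs_rate_treated=0.8, obs_rate_control=0.8)
        x = rng.normal(size=ds.n)
        ds = TrialDataset(ds.frame.assign(x=x), ("x",))
        all_observed = tuple(ds.frame.index[ds.s == 1])
        mono = monotonicity_check(ds, all_observed)
        obs = balance_test(ds, "observed-only")
        assert mono.wald_statistic == pytest.approx(obs.wald_statistic)
        assert mono.n_used == obs.n_used
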