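"""Trimming primitive, worst-case and trimming bounds, bootstrap intervals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trialbounds import (
    AnalysisConfig,
    ConditionalLeeBounds,
    HorowitzManskiBounds,
    LeeBounds,
    OutcomeSupport,
    TrialDataset,
    bounds_ci,
    conditional_lee_bounds,
    estimate_ate,
    horowitz_manski_bounds,
    lee_bounds,
    trimmed_mean,
)
from trialbounds.bounds import (
    BootstrapInstabilityError,
    ConditioningInfeasibleError,
    SupportError,
    lee_interval,
)

from conftest import make_trial


def oracle_trimmed_mean(values, p, tail, atoms=1000):
    """Independent oracle: expand each observation into equal-mass atoms and
    discard exactly the trimmed share of atoms from the named tail."""
    v = np.sort(np.repeat(np.asarray(values, float), atoms))
    k = int(round(p * v.size))
    if tail == "lower":
        return v[k:].mean()
    return v[: v.size - k].mean()


class TestTrimmedMean:
    def test_half_trim_from_lower_tail(self):
        assert trimmed_mean([1, 2, 3, 4], 0.5, "lower") == pytest.approx(3.5)

    def test_zero_trim_is_plain_mean(self):
        assert trimmed_mean([3.0, 7.0, 5.0], 0.0, "upper") == pytest.approx(5.0)

    def test_fractional_mass_on_straddling_order_statistic(self):
        # removing 30% of 5 observations discards v5 and half of v4
        expected = (1 + 2 + 3 + 0.5 * 4) / 3.5
        assert trimmed_mean([1, 2, 3, 4, 5], 0.3, "upper") == pytest.approx(expected)

    def test_integer_mode_trims_whole_observations(self):
        # ceil(0.3 * 5) = 2 observations removed
        assert trimmed_mean([1, 2, 3, 4, 5], 0.3, "upper", mode="integer") == pytest.approx(2.0)

    def test_row_order_never_matters(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=17)
        v[3:7] = v[3]  # ties
        for _ in range(5):
            w = rng.permutation(v)
            assert trimmed_mean(w, 0.23, "lower") == pytest.approx(
                trimmed_mean(v, 0.23, "lower")
            )

    @pytest.mark.parametrize("bad", [[], None])
    def test_empty_input_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            trimmed_mean(bad or [], 0.1, "lower")

    def test_full_trim_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([1.0, 2.0], 1.0, "lower")

    @given(
        values=st.lists(st.floats(-100, 100), min_size=2, max_size=40),
        # p on the 1/1000 grid so the atom oracle can discard exactly p mass
        p=st.integers(0, 900).map(lambda k: k / 1000),
        tail=st.sampled_from(["lower", "upper"]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_mass_discretization_oracle(self, values, p, tail):
        got = trimmed_mean(values, p, tail)
        assert got == pytest.approx(oracle_trimmed_mean(values, p, tail), abs=1e-3)

    @given(
        values=st.lists(st.floats(-50, 50), min_size=3, max_size=30),
        tail=st.sampled_from(["lower", "upper"]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_trim_fraction(self, values, tail):
        # trimming more of the lower tail can only raise the mean (and vice versa)
        grid = np.linspace(0, 0.9, 10)
        means = [trimmed_mean(values, p, tail) for p in grid]
        diffs = np.diff(means)
        if tail == "lower":
            assert (diffs >= -1e-9).all()
        else:
            assert (diffs <= 1e-9).all()


class TestHorowitzManski:
    def test_no_missing_collapses_to_point(self, balanced_covariate_dataset):
        ds = balanced_covariate_dataset
        sup = OutcomeSupport(float(ds.y.min()) - 1, float(ds.y.max()) + 1)
        res = horowitz_manski_bounds(ds, sup)
        beta = estimate_ate(ds).beta
        assert res.lower == pytest.approx(beta)
        assert res.upper == pytest.approx(beta)

    def test_hand_computed_two_by_two(self):
        y = np.array([50.0, np.nan, 60.0, 80.0])
        ds = TrialDataset.from_arrays(y, [1, 1, 0, 0])
        res = horowitz_manski_bounds(ds, OutcomeSupport(0, 100))
        assert res.lower == pytest.approx(-45.0)
        assert res.upper == pytest.approx(5.0)

    def test_wider_support_strictly_widens(self):
        y = np.array([50.0, np.nan, 60.0, 80.0])
        ds = TrialDataset.from_arrays(y, [1, 1, 0, 0])
        narrow = horowitz_manski_bounds(ds, OutcomeSupport(0, 100))
        wide = horowitz_manski_bounds(ds, OutcomeSupport(-50, 150))
        assert wide.lower < narrow.lower and wide.upper > narrow.upper

    def test_observed_outside_support_rejected(self):
        y = np.array([50.0, np.nan, 60.0, 120.0])
        ds = TrialDataset.from_arrays(y, [1, 1, 0, 0])
        with pytest.raises(SupportError):
            horowitz_manski_bounds(ds, OutcomeSupport(0, 100))


class TestLeeBounds:
    def test_hand_computed_toy(self, toy_lee_dataset):
        res = lee_bounds(toy_lee_dataset)
        assert res.trim_share == pytest.approx(0.5)
        assert res.trimmed_arm == "control"
        assert res.lower == pytest.approx(11.5)
        assert res.upper == pytest.approx(13.5)

    def test_equal_attrition_collapses_to_point_estimate(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=40)
        y[[0, 1, 20, 21]] = np.nan  # 2 of 20 missing in each arm
        ds = TrialDataset.from_arrays(y, [1] * 20 + [0] * 20)
        res = lee_bounds(ds)
        assert res.trim_share == 0.0
        beta = estimate_ate(ds).beta
        assert res.lower == pytest.approx(beta)
        assert res.upper == pytest.approx(beta)

    def test_trims_the_less_attrited_arm(self):
        # treated fully observed, control attrited: treated gets trimmed
        y = np.r_[np.arange(10.0), np.arange(10.0)]
        y[10:14] = np.nan
        ds = TrialDataset.from_arrays(y, [1] * 10 + [0] * 10)
        assert lee_bounds(ds).trimmed_arm == "treated"

    def test_interval_width_weakly_increasing_in_trim_share(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=60)
        other_mean = 0.7
        widths = []
        for p in np.linspace(0, 0.8, 17):
            lo, up = lee_interval(vals, other_mean, p, "control")
            widths.append(up - lo)
        assert (np.diff(widths) >= -1e-9).all()

    def test_trimmed_rows_exclude_both_tails(self, toy_lee_dataset):
        res = lee_bounds(toy_lee_dataset)
        kept = toy_lee_dataset.frame.loc[list(res.trimmed_rows)]
        control_kept = kept[kept.treatment == 0]["outcome"]
        # p = 0.5: only the middle straddlers of {1,2,3,4} survive both trims
        assert control_kept.between(2, 3).all()
        # untrimmed arm's observed rows all retained
        assert (kept.treatment == 1).sum() == 2


class TestConditionalLeeBounds:
    def test_single_cell_equals_unconditional(self, toy_lee_dataset):
        res = conditional_lee_bounds(toy_lee_dataset, ["all"] * 8)
        unc = lee_bounds(toy_lee_dataset)
        assert res.lower == pytest.approx(unc.lower)
        assert res.upper == pytest.approx(unc.upper)
        assert res.cells["weight"].sum() == pytest.approx(1.0)

    def test_exchangeable_cells_equal_unconditional(self, toy_lee_dataset):
        # two cells that are exact copies of the same trial
        f = toy_lee_dataset.frame
        doubled = TrialDataset(
            f.assign(participant_id=range(8)).pipe(
                lambda d: d._append(d.assign(participant_id=range(8, 16)), ignore_index=True)
            ),
            (),
        )
        cells = ["a"] * 8 + ["b"] * 8
        res = conditional_lee_bounds(doubled, cells)
        unc = lee_bounds(doubled)
        assert res.lower == pytest.approx(unc.lower)
        assert res.upper == pytest.approx(unc.upper)

    def test_attrition_confined_to_one_cell_tightens(self):
        # the gender thought-experiment: attrition only among "female"
        # participants, "male" outcomes sit mid-distribution -> the
        # conditional interval is strictly inside the unconditional one
        rng = np.random.default_rng(12)
        n = 400
        t = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        female = np.tile([1, 0], n // 2)
        y = np.where(female == 1, rng.normal(0, 3, n), rng.normal(0, 0.3, n)) + 2.0 * t
        s = np.ones(n, bool)
        drop = (t == 1) & (female == 1) & (rng.uniform(size=n) < 0.5)
        s[drop] = False
        ds = TrialDataset.from_arrays(
            np.where(s, y, np.nan), t, covariates={"female": female.astype(float)}
        )
        cond = conditional_lee_bounds(ds, female.astype(str))
        unc = lee_bounds(ds)
        assert cond.lower > unc.lower
        assert cond.upper < unc.upper

    def test_cell_missing_an_arm_is_infeasible(self):
        rng = np.random.default_rng(13)
        ds_big = make_trial(rng, n_treated=30, n_control=30, obs_rate_treated=1.0,
                            obs_rate_control=1.0)
        # a residual cell whose control outcomes are all missing
        y_tiny = np.r_[rng.normal(size=6), np.full(6, np.nan)]
        t_tiny = np.r_[np.ones(6, int), np.zeros(6, int)]
        f = ds_big.frame._append(
            TrialDataset.from_arrays(y_tiny, t_tiny).frame.assign(
                participant_id=range(1000, 1012)
            ),
            ignore_index=True,
        )
        ds = TrialDataset(f, ())
        cells = np.r_[["big"] * 60, ["tiny"] * 12]
        with pytest.raises(ConditioningInfeasibleError):
            conditional_lee_bounds(ds, cells, min_cell_per_arm=10)

    def test_small_cells_pool_into_other(self):
        rng = np.random.default_rng(14)
        ds = make_trial(rng, n_treated=60, n_control=60)
        # tiny cells straddle both arms (rows 50-59 treated, 60-69 control)
        cells = np.array(["big"] * 120, dtype=object)
        cells[50:60] = "tiny1"
        cells[60:70] = "tiny2"
        model = ConditionalLeeBounds(ds, cells, min_cell_per_arm=4)
        labels = set(model._labels)
        assert "tiny1" not in labels and "tiny2" not in labels
        assert "(other)" in labels or labels == {"big"}

    def test_flipped_cell_differential_trims_other_arm(self):
        rng = np.random.default_rng(15)
        # cell A: control more attrited; cell B: treated more attrited
        def block(n, obs_t, obs_c):
            y = rng.normal(size=2 * n)
            y[:n - obs_t] = np.nan
            y[n:2 * n - obs_c] = np.nan
            t = np.r_[np.ones(n, int), np.zeros(n, int)]
            return y, t
        ya, ta = block(40, 38, 25)
        yb, tb = block(40, 25, 38)
        ds = TrialDataset.from_arrays(np.r_[ya, yb], np.r_[ta, tb])
        cells = np.r_[["A"] * 80, ["B"] * 80]
        res = conditional_lee_bounds(ds, cells)
        detail = res.cells.set_index("cell")
        assert detail.loc["A", "trimmed_arm"] == "treated"
        assert detail.loc["B", "trimmed_arm"] == "control"


class TestBootstrapCi:
    def test_fixed_seed_is_bit_identical(self, toy_lee_dataset):
        cfg = AnalysisConfig(n_bootstrap=1, seed=42)
        a = bounds_ci(toy_lee_dataset, "lee", cfg)
        b = bounds_ci(toy_lee_dataset, "lee", cfg)
        assert a.ci_outer == b.ci_outer
        assert (a.se_lower, a.se_upper) == (b.se_lower, b.se_upper)

    def test_outer_ci_contains_identified_set(self):
        rng = np.random.default_rng(16)
        ds = make_trial(rng, obs_rate_treated=0.7, obs_rate_control=0.9)
        res = bounds_ci(ds, "lee", AnalysisConfig(n_bootstrap=100, seed=3))
        assert res.ci_outer[0] <= res.lower
        assert res.ci_outer[1] >= res.upper

    def test_no_attrition_ci_matches_classical_interval(self):
        rng = np.random.default_rng(17)
        ds = make_trial(rng, n_treated=1000, n_control=1000,
                        obs_rate_treated=1.0, obs_rate_control=1.0)
        res = bounds_ci(ds, "lee", AnalysisConfig(n_bootstrap=300, seed=4))
        ate = estimate_ate(ds)
        classical = ate.conf_int
        assert res.ci_outer[0] == pytest.approx(classical[0], abs=0.03)
        assert res.ci_outer[1] == pytest.approx(classical[1], abs=0.03)

    def test_imbens_manski_no_wider_than_outer(self):
        rng = np.random.default_rng(18)
        ds = make_trial(rng, obs_rate_treated=0.6, obs_rate_control=0.9)
        cfg = AnalysisConfig(n_bootstrap=200, seed=5)
        outer = bounds_ci(ds, "lee", cfg)
        im = bounds_ci(ds, "lee", cfg, ci_method="imbens-manski")
        assert im.ci_width <= outer.ci_width + 1e-12
        assert im.ci_outer[0] <= im.lower and im.ci_outer[1] >= im.upper

    def test_unstable_bootstrap_raises(self):
        # a single observed control outcome vanishes from ~33% of replicates
        y = np.r_[np.arange(5.0), 1.0, np.full(4, np.nan)]
        ds = TrialDataset.from_arrays(y, [1] * 5 + [0] * 5)
        with pytest.raises(BootstrapInstabilityError):
            LeeBounds(ds).fit(n_bootstrap=100, seed=0)

    def test_hm_bootstrap_runs(self):
        rng = np.random.default_rng(19)
        ds = make_trial(rng, obs_rate_treated=0.8, obs_rate_control=0.95)
        sup = OutcomeSupport(np.nanmin(ds.y) - 1, np.nanmax(ds.y) + 1)
        res = bounds_ci(ds, "hm", AnalysisConfig(n_bootstrap=50, seed=6), support=sup)
        assert res.ci_outer[0] <= res.lower <= res.upper <= res.ci_outer[1]

    def test_summary_renders(self, toy_lee_dataset):
        res = bounds_ci(toy_lee_dataset, "lee", AnalysisConfig(n_bootstrap=20, seed=1))
        text = res.summary()
        assert "lee" in text and "Lower bound" in text
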