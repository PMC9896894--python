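import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleodecay import (
    AnalyteSeries,
    PowerDecayModel,
    fit_power,
    fit_exponential,
    fit_linear,
    compare_models,
    flag_fit,
    half_life,
    calibrate_k_from_h1,
    half_life_schedule,
    summarize_decay,
    TABLE_AGES,
)
from paleodecay.kinetics import InsufficientDataError
from helpers import grid_search_slope


def series(t, y, **kw):
    return AnalyteSeries("s", np.asarray(t, float), np.asarray(y, float), **kw)


class TestPowerFit:
    def test_exact_power_law(self, exact_power_series):
        f = fit_power(exact_power_series)
        assert f.amplitude == pytest.approx(100.0)
        assert f.exponent == pytest.approx(-1.0)
        assert f.decay_constant == pytest.approx(1.0)
        assert f.r_squared == pytest.approx(1.0)
        assert not f.flagged

    def test_constant_series_has_zero_decay(self):
        f = fit_power(series([1, 10, 100], [10, 10, 10]))
        assert f.exponent == 0.0
        assert f.decay_constant == 0.0
        assert f.r_squared == 0.0
        assert f.p_slope == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_slope_matches_grid_search_oracle(self, noisy_series_factory, seed):
        s = noisy_series_factory(seed)
        f = fit_power(s)
        oracle = grid_search_slope(np.log(s.ages), np.log(s.values))
        assert f.exponent == pytest.approx(oracle, abs=1e-6)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError, match="insufficient"):
            fit_power(series([1, 2], [3, 2]))

    def test_zero_values_excluded_and_counted(self):
        f = fit_power(series([1, 2, 4, 8], [8, 4, 0, 1]))
        assert f.n_points == 3
        assert f.n_excluded == 1

    def test_pseudo_value_policy_keeps_zeros(self):
        f = fit_power(series([1, 2, 4, 8], [8, 4, 0, 1]), zero_policy="pseudo")
        assert f.n_points == 4

    def test_surface_age_excluded(self):
        f = fit_power(series([0, 1, 10, 100], [200, 100, 10, 1]))
        assert f.n_points == 3

    def test_nls_method_close_to_ols_on_clean_data(self, exact_power_series):
        f = fit_power(exact_power_series, method="nls")
        assert f.exponent == pytest.approx(-1.0, abs=1e-6)
        assert f.decay_constant == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(0.01, 1e6), st.integers(0, 1000))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        t = np.geomspace(1, 100, 10)
        y = 50 * t ** -0.8 * np.exp(rng.normal(0, 0.3, 10))
        f1 = fit_power(series(t, y))
        f2 = fit_power(series(t, c * y))
        assert f2.exponent == pytest.approx(f1.exponent, rel=1e-9)
        assert f2.r_squared == pytest.approx(f1.r_squared, rel=1e-9)
        assert f2.p_slope == pytest.approx(f1.p_slope, rel=1e-6)
        assert f2.amplitude == pytest.approx(c * f1.amplitude, rel=1e-9)


class TestOtherModels:
    def test_exact_exponential(self):
        t = np.array([0.0, 10.0, 20.0])
        f = fit_exponential(series(t, 50 * np.exp(-0.1 * t)))
        assert f.exponent == pytest.approx(-0.1)
        assert f.amplitude == pytest.approx(50.0)
        assert f.r_squared == pytest.approx(1.0)
        assert f.decay_constant is None

    def test_exponential_constant(self):
        assert fit_exponential(series([0, 1, 2], [5, 5, 5])).exponent == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exponential_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 50, 15)
        y = 20 * np.exp(-0.05 * t + rng.normal(0, 0.2, 15))
        f = fit_exponential(series(t, y))
        oracle = grid_search_slope(t, np.log(y), lo=-1, hi=1)
        assert f.exponent == pytest.approx(oracle, abs=1e-6)

    def test_exact_linear(self):
        f = fit_linear(series([1, 2, 3], [9.5, 9.0, 8.5]))
        assert f.exponent == pytest.approx(-0.5)
        assert f.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(1, 100, 12)
        y = 10 - 0.03 * t + rng.normal(0, 0.5, 12)
        f = fit_linear(series(t, y))
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert f.exponent == pytest.approx(beta[1], abs=1e-9)
        assert f.amplitude == pytest.approx(beta[0], abs=1e-9)


class TestCompareModels:
    def test_exact_power_wins(self, exact_power_series):
        cmp_ = compare_models(exact_power_series)
        assert cmp_.best == "power"
        assert cmp_.fits["power"].r_squared == pytest.approx(1.0)

    def test_exact_line_wins(self):
        t = np.linspace(1, 30, 10)
        cmp_ = compare_models(series(t, 100 - 2 * t))
        assert cmp_.best == "linear"
        assert cmp_.fits["linear"].r_squared == pytest.approx(1.0)

    def test_ranking_order_and_tiebreak(self, exact_power_series):
        cmp_ = compare_models(exact_power_series)
        assert cmp_.ranking[0] == "power"
        assert set(cmp_.ranking) == {"power", "exponential", "linear"}


class TestFlagRule:
    @pytest.mark.parametrize("p,r2,expected", [
        (0.2, 0.5, True),     # nonsignificant slope
        (0.01, 0.1, True),    # low R^2
        (0.01, 0.9, False),
        (0.05, 0.2, False),   # boundaries are not flagged (strict rule)
    ])
    def test_flag(self, p, r2, expected):
        assert flag_fit(p, r2) is expected


class TestHalfLife:
    def test_k1_half_life_equals_age(self):
        assert half_life(1.0, 10.0) == pytest.approx(10.0)

    def test_calibrated_077_at_age_100(self):
        k = calibrate_k_from_h1(0.77)
        assert half_life(k, 100.0) == pytest.approx(77.0)

    def test_k2_closed_form(self):
        assert half_life(2.0, 100.0) == pytest.approx(100 * (math.sqrt(2) - 1))

    def test_instantaneous_rate_variant(self):
        assert half_life(2.0, 100.0, "instantaneous_rate") == pytest.approx(
            math.log(2) * 50)
        k = calibrate_k_from_h1(5.0, "instantaneous_rate")
        assert half_life(k, 1.0, "instantaneous_rate") == pytest.approx(5.0)

    def test_nonpositive_k_gives_infinity(self):
        with pytest.warns(UserWarning, match="no decay"):
            assert half_life(0.0, 10.0) == math.inf

    def test_vascular_plant_schedule_value(self):
        k = calibrate_k_from_h1(3615.0)
        assert half_life(k, 200.0) == pytest.approx(7.23e5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.05, 10), st.floats(0.1, 1e4), st.floats(0.1, 100))
    def test_linearity_in_age(self, k, t, c):
        assert half_life(k, c * t) == pytest.approx(c * half_life(k, t),
                                                    rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.05, 5), st.floats(0.1, 5), st.floats(1, 1000))
    def test_monotone_decreasing_in_k(self, k, dk, t):
        assert half_life(k + dk, t) < half_life(k, t)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(1e-3, 1e5), st.sampled_from(["exact_halving",
                                                  "instantaneous_rate"]))
    def test_calibration_round_trip(self, h1, formula):
        k = calibrate_k_from_h1(h1, formula)
        assert half_life(k, 1.0, formula) == pytest.approx(h1, rel=1e-12)


class TestSchedule:
    def test_k1_schedule_equals_ages(self):
        s = half_life_schedule(1.0)
        assert s.half_lives == pytest.approx(TABLE_AGES)

    def test_fatty_acid_row(self):
        k = calibrate_k_from_h1(2.82)
        s = half_life_schedule(k)
        assert s.half_lives == pytest.approx(
            [2.82, 56.4, 141, 282, 564, 1410, 2820], rel=1e-12)

    def test_ratio_constant_across_schedule(self):
        s = half_life_schedule(0.37)
        ratios = np.array(s.half_lives) / np.array(s.ages)
        assert np.ptp(ratios) == pytest.approx(0.0, abs=1e-9)

    def test_as_row_shape(self):
        row = half_life_schedule(1.0).as_row()
        assert row["hl_age_1"] == pytest.approx(1.0)
        assert row["hl_age_1000"] == pytest.approx(1000.0)


class TestSummaries:
    def _fits(self, ks, group="diatom"):
        out = []
        for k in ks:
            t = np.geomspace(1, 100, 5)
            f = fit_power(series(t, 10 * t ** -k, organism_group=group))
            out.append(f)
        return out

    def test_mean_and_sd(self):
        fits = self._fits([1.0, 2.0, 3.0])
        (summ,) = summarize_decay(fits, "organism_group")
        assert summ.mean_k == pytest.approx(2.0)
        assert summ.sd_k == pytest.approx(1.0)
        assert summ.n_fits == 3

    def test_single_fit_group(self):
        (summ,) = summarize_decay(self._fits([0.5]), "organism_group")
        assert summ.mean_k == pytest.approx(0.5)
        assert summ.sd_k == 0.0

    def test_non_decreasing_group_marked_not_applicable(self):
        t = np.geomspace(1, 100, 5)
        f = fit_power(series(t, 10 * t ** 0.3))  # increases with age
        (summ,) = summarize_decay([f], "organism_group")
        assert not summ.applicable

    def test_synthetic_mean_recovery(self, noisy_series_factory):
        ks = [fit_power(noisy_series_factory(seed, b=-1.2)).decay_constant
              for seed in range(100)]
        se = np.std(ks, ddof=1) / 10.0
        assert abs(np.mean(ks) - 1.2) < 2 * se + 0.02
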