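"""Forecaster recursions: hand-computed steps, degeneracies, fixed points,
and agreement with an independent step-by-step re-implementation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmdemand import (
    SmoothingParams,
    demand_driven_forecast,
    fit_double_exp,
    fit_holt_linear,
    fit_hw_additive,
    fit_hw_multiplicative,
    fit_hw_no_trend,
    fit_method,
    fit_moving_average,
    fit_naive,
    fit_ses,
)

from conftest import series

# --------------------------------------------------------------- oracles
# Deliberately naive re-implementations that store every component
# explicitly, used only to cross-check the package's recursions.


def oracle_ses(y, alpha):
    f = [np.nan, y[0]]
    for t in range(2, len(y)):
        f.append(alpha * y[t - 1] + (1 - alpha) * f[-1])
    return np.array(f)


def oracle_hw(y, alpha, beta, gamma, P, multiplicative, a0, b0, seas0):
    seas = list(seas0)
    a, b = a0, b0
    fitted = [np.nan]
    for i in range(1, len(y)):
        ph = i % P
        if multiplicative:
            fitted.append((a + b) * seas[ph])
            a_new = alpha * (y[i] / seas[ph]) + (1 - alpha) * (a + b)
        else:
            fitted.append(a + b + seas[ph])
            a_new = alpha * (y[i] - seas[ph]) + (1 - alpha) * (a + b)
        b = beta * (a_new - a) + (1 - beta) * b
        if multiplicative:
            seas[ph] = gamma * (y[i] / a_new) + (1 - gamma) * seas[ph]
        else:
            seas[ph] = gamma * (y[i] - a_new) + (1 - gamma) * seas[ph]
        a = a_new
    return np.array(fitted)


def oracle_double(y, alpha, gamma):
    s1, s2 = y[0], y[0]
    fitted = [np.nan]
    for i in range(1, len(y)):
        level, trend = 2 * s1 - s2, alpha / (1 - alpha) * (s1 - s2)
        fitted.append(level + trend)
        s1 = alpha * y[i] + (1 - alpha) * s1
        s2 = gamma * s1 + (1 - gamma) * s2
    return np.array(fitted)


# ------------------------------------------------------------ hand steps


class TestNaive:
    def test_chain_week2_equals_week1_actual(self, chain_no_shortage):
        tr = fit_naive(chain_no_shortage)
        assert tr.fitted[1] == 21819

    def test_constant_series(self):
        tr = fit_naive(series([5, 5, 5]))
        np.testing.assert_allclose(tr.fitted[1:], 5)

    def test_two_point_rule(self):
        tr = fit_naive(series([10, 20]), SmoothingParams(horizon=3))
        assert tr.fitted[1] == 10
        np.testing.assert_allclose(tr.future, [20, 20, 20])

    def test_rejects_shortage_weeks(self, chain_shortage):
        with pytest.raises(ValueError, match="impute"):
            fit_naive(chain_shortage)


class TestMovingAverage:
    def test_chain_week11(self, chain_no_shortage):
        tr = fit_moving_average(chain_no_shortage, SmoothingParams(window=2))
        assert tr.fitted[10] == pytest.approx((18986 + 24854) / 2)  # 21920

    def test_hand_example(self):
        tr = fit_moving_average(series([2, 4, 6]), SmoothingParams(window=2))
        assert tr.fitted[2] == 3
        assert tr.future[0] == 5

    def test_window_one_equals_naive(self, chain_no_shortage):
        ma = fit_moving_average(chain_no_shortage, SmoothingParams(window=1))
        nv = fit_naive(chain_no_shortage)
        np.testing.assert_allclose(ma.fitted[1:], nv.fitted[1:])

    def test_window_too_large(self):
        with pytest.raises(ValueError, match="window"):
            fit_moving_average(series([1, 2, 3]), SmoothingParams(window=3))

    def test_warmup_weeks_undefined(self, chain_no_shortage):
        tr = fit_moving_average(chain_no_shortage, SmoothingParams(window=2))
        assert np.isnan(tr.fitted[:2]).all()
        assert tr.n_defined == 11


class TestSes:
    def test_chain_week3_recursion(self, chain_no_shortage):
        tr = fit_ses(chain_no_shortage, SmoothingParams(alpha=0.2))
        assert tr.fitted[2] == pytest.approx(0.2 * 22344 + 0.8 * 21819)  # 21924

    def test_alpha_one_equals_naive(self, chain_no_shortage):
        s = fit_ses(chain_no_shortage, SmoothingParams(alpha=1.0))
        n = fit_naive(chain_no_shortage)
        np.testing.assert_allclose(s.fitted[1:], n.fitted[1:])

    def test_one_step_by_hand(self):
        tr = fit_ses(series([10, 20]), SmoothingParams(alpha=0.5))
        assert tr.fitted[1] == 10
        assert tr.future[0] == 15

    def test_matches_reference_oracle(self, chain_no_shortage):
        tr = fit_ses(chain_no_shortage, SmoothingParams(alpha=0.2))
        np.testing.assert_allclose(
            tr.fitted[1:], oracle_ses(chain_no_shortage.values, 0.2)[1:], rtol=1e-12
        )

    def test_matches_statsmodels(self, chain_no_shortage):
        sm = pytest.importorskip("statsmodels.tsa.holtwinters")
        y = chain_no_shortage.values
        fit = sm.SimpleExpSmoothing(
            y, initialization_method="known", initial_level=y[0]
        ).fit(smoothing_level=0.2, optimized=False)
        ours = fit_ses(chain_no_shortage, SmoothingParams(alpha=0.2))
        np.testing.assert_allclose(ours.fitted[1:], fit.fittedvalues[1:], rtol=1e-9)


class TestHoltLinear:
    def test_hand_recursion(self):
        tr = fit_holt_linear(
            series([12, 14, 17]),
            SmoothingParams(alpha=0.4, beta=0.7),
            level_init=12,
            trend_init=2,
        )
        # a2 = 0.4*14 + 0.6*14 = 14, b2 = 0.7*2 + 0.3*2 = 2, so F3 = 16
        assert tr.fitted[1] == pytest.approx(14.0)
        assert tr.fitted[2] == pytest.approx(16.0)

    def test_exactly_linear_series_is_fixed_point(self):
        y = 100 + 10 * np.arange(1, 14)
        tr = fit_holt_linear(
            series(y), SmoothingParams(alpha=0.4, beta=0.7), level_init=110, trend_init=10
        )
        np.testing.assert_allclose(tr.fitted[1:], y[1:], rtol=1e-12)
        np.testing.assert_allclose(tr.future[0], y[-1] + 10, rtol=1e-12)

    def test_beta_zero_reduces_to_ses(self, chain_no_shortage):
        holt = fit_holt_linear(
            chain_no_shortage,
            SmoothingParams(alpha=0.2, beta=0.0),
            level_init=chain_no_shortage.values[0],
            trend_init=0.0,
        )
        ses = fit_ses(chain_no_shortage, SmoothingParams(alpha=0.2))
        np.testing.assert_allclose(holt.fitted[1:], ses.fitted[1:], rtol=1e-12)

    def test_needs_three_weeks(self):
        with pytest.raises(ValueError):
            fit_holt_linear(series([1, 2]))


class TestHwNoTrend:
    def test_flat_series_fixed_point(self):
        tr = fit_hw_no_trend(series([7.0] * 8), SmoothingParams(alpha=0.2, gamma=0.05))
        np.testing.assert_allclose(tr.fitted[1:], 7.0)
        np.testing.assert_allclose(tr.future, 7.0)

    def test_gamma_zero_zero_seasonal_reduces_to_ses(self, chain_no_shortage):
        hw = fit_hw_no_trend(chain_no_shortage, SmoothingParams(alpha=0.2, gamma=0.0))
        ses = fit_ses(chain_no_shortage, SmoothingParams(alpha=0.2))
        np.testing.assert_allclose(hw.fitted[1:], ses.fitted[1:], rtol=1e-12)

    def test_period_two_cycle_fixed_point(self):
        tr = fit_hw_no_trend(
            series([10, 20, 10, 20]),
            SmoothingParams(alpha=0.2, gamma=0.05, period=2),
            level_init=15,
            seasonal_init=[-5, 5],
        )
        np.testing.assert_allclose(tr.fitted[1:], [20, 10, 20], rtol=1e-12)
        assert tr.future[0] == pytest.approx(10.0)  # week 5 continues the cycle


class TestHwAdditive:
    def test_one_step_by_hand(self):
        tr = fit_hw_additive(
            series([10, 12]),
            SmoothingParams(alpha=0.2, beta=0.15, gamma=0.05, period=1),
            level_init=10,
            trend_init=2,
        )
        assert tr.fitted[1] == pytest.approx(12.0)
        assert tr.components["level"] == pytest.approx(0.2 * 12 + 0.8 * 12)

    def test_gamma_zero_reduces_to_holt(self, chain_no_shortage):
        hw = fit_hw_additive(chain_no_shortage, SmoothingParams(alpha=0.4, beta=0.7, gamma=0.0))
        holt = fit_holt_linear(chain_no_shortage, SmoothingParams(alpha=0.4, beta=0.7))
        np.testing.assert_allclose(hw.fitted[1:], holt.fitted[1:], rtol=1e-12)

    def test_linear_plus_cycle_fixed_point(self):
        y = 100 + 5 * np.arange(1, 11) + np.resize([-3, 3], 10)
        tr = fit_hw_additive(
            series(y),
            SmoothingParams(alpha=0.2, beta=0.15, gamma=0.05, period=2),
            level_init=105,
            trend_init=5,
            seasonal_init=[-3, 3],
        )
        np.testing.assert_allclose(tr.fitted[1:], y[1:], rtol=1e-12)


class TestHwMultiplicative:
    def test_unit_seasonals_gamma_zero_reduce_to_holt(self, chain_no_shortage):
        hw = fit_hw_multiplicative(
            chain_no_shortage, SmoothingParams(alpha=0.4, beta=0.7, gamma=0.0)
        )
        holt = fit_holt_linear(chain_no_shortage, SmoothingParams(alpha=0.4, beta=0.7))
        np.testing.assert_allclose(hw.fitted[1:], holt.fitted[1:], rtol=1e-12)

    def test_multiplicative_cycle_fixed_point(self):
        level = 100 + 5 * np.arange(1, 11)
        y = level * np.resize([0.8, 1.25], 10)
        tr = fit_hw_multiplicative(
            series(y),
            SmoothingParams(alpha=0.2, beta=0.15, gamma=0.05, period=2),
            level_init=105,
            trend_init=5,
            seasonal_init=[0.8, 1.25],
        )
        np.testing.assert_allclose(tr.fitted[1:], y[1:], rtol=1e-10)

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError, match="impute"):
            fit_hw_multiplicative(series([5, 0.0001, 7]))  # sentinel still masked
        with pytest.raises(ValueError, match="week 2"):
            fit_hw_multiplicative(series([5, 0, 7]).drop_mask())  # true zero

    def test_positive_output_on_positive_input(self, panel_8x13):
        for s in panel_8x13:
            tr = fit_hw_multiplicative(s)
            assert np.all(tr.fitted[1:] > 0)


class TestDoubleExp:
    def test_constant_series(self):
        tr = fit_double_exp(series([9.0] * 6))
        np.testing.assert_allclose(tr.fitted[1:], 9.0)
        assert tr.components["trend"] == pytest.approx(0.0)
        np.testing.assert_allclose(tr.future, 9.0)

    def test_hand_step(self):
        tr = fit_double_exp(series([10, 20]), SmoothingParams(alpha=0.2, gamma=0.15))
        # S1 = 12, S2 = 10.3 after week 2 -> level 13.7, trend 0.425
        assert tr.components["level"] == pytest.approx(13.7)
        assert tr.components["trend"] == pytest.approx(0.425)
        assert tr.future[0] == pytest.approx(13.7 + 0.425)

    def test_gamma_equals_alpha_is_classical_brown(self, chain_no_shortage):
        y = chain_no_shortage.values
        tr = fit_double_exp(chain_no_shortage, SmoothingParams(alpha=0.3, gamma=0.3))
        np.testing.assert_allclose(tr.fitted[1:], oracle_double(y, 0.3, 0.3)[1:], rtol=1e-12)

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            fit_double_exp(series([1, 2, 3]), SmoothingParams(alpha=1.0, gamma=0.15))


class TestDemandDriven:
    @pytest.mark.parametrize(
        "patients,penetration,avg,expected",
        [(0, 0.5, 10, 0), (100, 0.2, 3, 60), (1, 1, 7.5, 7.5)],
    )
    def test_product_rule(self, patients, penetration, avg, expected):
        assert demand_driven_forecast(patients, penetration, avg) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            demand_driven_forecast(-1, 0.5, 10)
        with pytest.raises(ValueError):
            demand_driven_forecast(10, 1.5, 10)


# ----------------------------------------------------------- properties


@given(c=st.floats(min_value=1.0, max_value=1e5), n=st.integers(4, 20))
@settings(max_examples=30, deadline=None)
def test_every_method_forecasts_a_constant(c, n):
    """A constant positive series is a fixed point of every recursion."""
    s = series([c] * n)
    for name in ("naive", "moving_average", "ses", "double_exp", "hw_no_trend"):
        tr = fit_method(name, s)
        defined = tr.fitted[~np.isnan(tr.fitted)]
        np.testing.assert_allclose(defined, c, rtol=1e-9)
        np.testing.assert_allclose(tr.future, c, rtol=1e-9)
    for name in ("holt_linear", "hw_additive", "hw_multiplicative"):
        tr = fit_method(name, s, level_init=c, trend_init=0.0)
        np.testing.assert_allclose(tr.fitted[1:], c, rtol=1e-9)
        np.testing.assert_allclose(tr.future, c, rtol=1e-9)


def test_recursions_match_explicit_oracle_on_random_series():
    """50 random positive series: package recursions vs the step-by-step
    re-implementations agree to 1e-9."""
    rng = np.random.default_rng(7)
    for rep in range(50):
        y = rng.uniform(50, 500, size=rng.integers(6, 20))
        s = series(y)
        al, be, ga, P = 0.2, 0.15, 0.05, int(rng.integers(1, 4))
        params = SmoothingParams(alpha=al, beta=be, gamma=ga, period=P)

        hw_add = fit_hw_additive(s, params, init="first_observation")
        ora = oracle_hw(y, al, be, ga, P, False, y[0], 0.0, [0.0] * P)
        np.testing.assert_allclose(hw_add.fitted[1:], ora[1:], rtol=1e-9)

        hw_mul = fit_hw_multiplicative(s, params, init="first_observation")
        ora = oracle_hw(y, al, be, ga, P, True, y[0], 0.0, [1.0] * P)
        np.testing.assert_allclose(hw_mul.fitted[1:], ora[1:], rtol=1e-9)

        hw_nt = fit_hw_no_trend(s, params)
        ora = oracle_hw(y, al, 0.0, ga, P, False, y[0], 0.0, [0.0] * P)
        np.testing.assert_allclose(hw_nt.fitted[1:], ora[1:], rtol=1e-9)

        dbl = fit_double_exp(s, SmoothingParams(alpha=0.2, gamma=0.15))
        np.testing.assert_allclose(dbl.fitted[1:], oracle_double(y, 0.2, 0.15)[1:], rtol=1e-9)


def test_all_fitted_values_finite(panel_8x13):
    for s in panel_8x13:
        for name in ("naive", "moving_average", "ses", "double_exp",
                     "holt_linear", "hw_no_trend", "hw_additive", "hw_multiplicative"):
            tr = fit_method(name, s)
            assert np.isfinite(tr.fitted[~np.isnan(tr.fitted)]).all()
            assert np.isfinite(tr.future).all()
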