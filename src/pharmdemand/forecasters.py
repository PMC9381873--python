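"""The eight weekly-sales forecasting methods.

All methods operate on a :class:`~pharmdemand.timeseries.WeeklySeries` with
no shortage weeks (impute first — see :mod:`pharmdemand.cleaning`) and return
a :class:`~pharmdemand.timeseries.ForecastTrace` whose ``fitted`` array holds
the one-step-ahead forecast for each week (NaN on warm-up weeks) and whose
``future`` array holds the forecasts for the next ``horizon`` weeks.

Conventions
-----------
* Warm-up: the naive, single-exponential and all recursive smoothers cannot
  forecast week 1 (``fitted[0]`` is NaN); a moving average of window ``w``
  cannot forecast weeks ``1..w``.
* Initialisation of the Holt family is configurable: ``"ols_on_first_m"``
  (default, a straight line through the first ``m=2`` observations),
  ``"first_observation"`` (level = first value, zero trend), or explicit
  ``level_init`` / ``trend_init`` / ``seasonal_init`` values.  Explicit and
  data-driven initialisation both define the smoothing state *at week 1*;
  the recursion then runs from week 2.
* Seasonal factors default to 0 (additive) or 1 (multiplicative) when not
  supplied; the seasonal period defaults to 1.
* Negative forecasts are returned as computed (a real possibility after a
  shortage collapses the trend); callers may floor them if they wish.
"""

from __future__ import annotations

import numpy as np

from .timeseries import ForecastTrace, SmoothingParams, WeeklySeries

__all__ = [
    "fit_naive",
    "fit_moving_average",
    "fit_ses",
    "fit_double_exp",
    "fit_holt_linear",
    "fit_hw_no_trend",
    "fit_hw_additive",
    "fit_hw_multiplicative",
    "demand_driven_forecast",
    "METHODS",
    "DEFAULT_PARAMS",
    "fit_method",
]


def _require_complete(series: WeeklySeries) -> np.ndarray:
    if series.has_missing:
        raise ValueError(
            f"series {series.series_id!r} has shortage weeks "
            f"{series.weeks[series.missing_mask].tolist()}; impute them first "
            "(pharmdemand.cleaning.impute_missing)"
        )
    return series.values


def _trace(series, name, fitted, future, components=None) -> ForecastTrace:
    return ForecastTrace(
        method_name=name,
        weeks=series.weeks.copy(),
        fitted=np.asarray(fitted, dtype=float),
        future=np.asarray(future, dtype=float),
        components=components or {},
    )


def fit_naive(series: WeeklySeries, params: SmoothingParams | None = None) -> ForecastTrace:
    """Naive (random-walk) forecast: every prediction is the last observation."""
    y = _require_complete(series)
    if len(y) < 2:
        raise ValueError("naive method needs at least 2 weeks")
    params = params or SmoothingParams()
    fitted = np.full(len(y), np.nan)
    fitted[1:] = y[:-1]
    future = np.full(params.horizon, y[-1])
    return _trace(series, "naive", fitted, future, {"level": y[-1]})


def fit_moving_average(
    series: WeeklySeries, params: SmoothingParams | None = None
) -> ForecastTrace:
    """Moving average of the previous ``window`` weeks."""
    y = _require_complete(series)
    params = params or SmoothingParams(window=2)
    w = params.window
    if w >= len(y):
        raise ValueError(f"window {w} must be smaller than the series length {len(y)}")
    fitted = np.full(len(y), np.nan)
    for i in range(w, len(y)):
        fitted[i] = y[i - w : i].mean()
    last = y[-w:].mean()
    future = np.full(params.horizon, last)
    return _trace(series, "moving_average", fitted, future, {"level": last})


def fit_ses(series: WeeklySeries, params: SmoothingParams | None = None) -> ForecastTrace:
    """Single exponential smoothing, ``F[t+1] = alpha*Y[t] + (1-alpha)*F[t]``.

    Initialised with ``F[2] = Y[1]`` (the first forecast equals the first
    observation), so week 1 is the only warm-up week.
    """
    y = _require_complete(series)
    if len(y) < 2:
        raise ValueError("single exponential smoothing needs at least 2 weeks")
    params = params or SmoothingParams(alpha=0.2)
    a = params.alpha
    fitted = np.full(len(y), np.nan)
    f = y[0]
    fitted[1] = f
    for i in range(2, len(y)):
        f = a * y[i - 1] + (1 - a) * f
        fitted[i] = f
    nxt = a * y[-1] + (1 - a) * f
    future = np.full(params.horizon, nxt)
    return _trace(series, "ses", fitted, future, {"level": nxt})


def _holt_init(y, params, init, level_init, trend_init, m):
    """Level/trend state at week 1 for the Holt family."""
    if level_init is not None or trend_init is not None:
        a0 = y[0] if level_init is None else float(level_init)
        b0 = 0.0 if trend_init is None else float(trend_init)
        return a0, b0
    if init == "first_observation":
        return float(y[0]), 0.0
    if init == "ols_on_first_m":
        m = min(max(int(m), 2), len(y))
        slope, intercept = np.polyfit(np.arange(1, m + 1), y[:m], 1)
        return float(intercept + slope), float(slope)
    raise ValueError(f"unknown init method {init!r}")


def fit_holt_linear(
    series: WeeklySeries,
    params: SmoothingParams | None = None,
    init: str = "ols_on_first_m",
    level_init: float | None = None,
    trend_init: float | None = None,
    init_m: int = 2,
) -> ForecastTrace:
    """Holt's linear trend method (level + trend smoothing equations)."""
    y = _require_complete(series)
    if len(y) < 3:
        raise ValueError("Holt's linear method needs at least 3 weeks")
    params = params or SmoothingParams(alpha=0.4, beta=0.7)
    al, be = params.alpha, params.beta
    a, b = _holt_init(y, params, init, level_init, trend_init, init_m)
    fitted = np.full(len(y), np.nan)
    for i in range(1, len(y)):
        fitted[i] = a + b
        a_new = al * y[i] + (1 - al) * (a + b)
        b = be * (a_new - a) + (1 - be) * b
        a = a_new
    future = a + np.arange(1, params.horizon + 1) * b
    return _trace(series, "holt_linear", fitted, future, {"level": a, "trend": b})


def _seasonal_init(seasonal_init, period, neutral):
    if seasonal_init is None:
        return np.full(period, float(neutral))
    seas = np.asarray(seasonal_init, dtype=float).copy()
    if len(seas) != period:
        raise ValueError(f"seasonal_init must have length period={period}")
    return seas


def fit_hw_no_trend(
    series: WeeklySeries,
    params: SmoothingParams | None = None,
    level_init: float | None = None,
    seasonal_init=None,
) -> ForecastTrace:
    """Holt-Winters without trend: level + additive seasonal factors only."""
    y = _require_complete(series)
    params = params or SmoothingParams(alpha=0.2, gamma=0.05)
    al, ga, P = params.alpha, params.gamma, params.period
    if len(y) < P + 1:
        raise ValueError(f"need at least period+1 = {P + 1} weeks")
    seas = _seasonal_init(seasonal_init, P, 0.0)
    a = float(level_init) if level_init is not None else y[0] - seas[0]
    fitted = np.full(len(y), np.nan)
    for i in range(1, len(y)):
        ph = i % P  # phase of week i+1 (1-based week w has phase (w-1) % P)
        fitted[i] = a + seas[ph]
        a_new = al * (y[i] - seas[ph]) + (1 - al) * a
        seas[ph] = ga * (y[i] - a_new) + (1 - ga) * seas[ph]
        a = a_new
    ks = np.arange(1, params.horizon + 1)
    future = a + seas[(len(y) + ks - 1) % P]
    return _trace(series, "hw_no_trend", fitted, future, {"level": a, "seasonal": seas})


def fit_hw_additive(
    series: WeeklySeries,
    params: SmoothingParams | None = None,
    init: str = "ols_on_first_m",
    level_init: float | None = None,
    trend_init: float | None = None,
    seasonal_init=None,
    init_m: int = 2,
) -> ForecastTrace:
    """Holt-Winters with additive seasonality and a linear trend."""
    y = _require_complete(series)
    params = params or SmoothingParams(alpha=0.2, beta=0.15, gamma=0.05)
    al, be, ga, P = params.alpha, params.beta, params.gamma, params.period
    if len(y) < P + 1:
        raise ValueError(f"need at least period+1 = {P + 1} weeks")
    seas = _seasonal_init(seasonal_init, P, 0.0)
    a, b = _holt_init(y - np.resize(seas, len(y)), params, init, level_init, trend_init, init_m)
    fitted = np.full(len(y), np.nan)
    for i in range(1, len(y)):
        ph = i % P
        fitted[i] = a + b + seas[ph]
        a_new = al * (y[i] - seas[ph]) + (1 - al) * (a + b)
        b = be * (a_new - a) + (1 - be) * b
        seas[ph] = ga * (y[i] - a_new) + (1 - ga) * seas[ph]
        a = a_new
    ks = np.arange(1, params.horizon + 1)
    future = a + ks * b + seas[(len(y) + ks - 1) % P]
    return _trace(
        series, "hw_additive", fitted, future, {"level": a, "trend": b, "seasonal": seas}
    )


def fit_hw_multiplicative(
    series: WeeklySeries,
    params: SmoothingParams | None = None,
    init: str = "ols_on_first_m",
    level_init: float | None = None,
    trend_init: float | None = None,
    seasonal_init=None,
    init_m: int = 2,
) -> ForecastTrace:
    """Holt-Winters with multiplicative seasonality and a linear trend.

    Requires strictly positive values; shortage sentinels must have been
    imputed away and true zeros make the seasonal ratios undefined.
    """
    y = _require_complete(series)
    if np.any(y <= 0):
        wk = series.weeks[np.flatnonzero(y <= 0)[0]]
        raise ValueError(
            f"multiplicative seasonality undefined for non-positive value at week {wk}; "
            "impute shortage sentinels first"
        )
    params = params or SmoothingParams(alpha=0.2, beta=0.15, gamma=0.05)
    al, be, ga, P = params.alpha, params.beta, params.gamma, params.period
    if len(y) < P + 1:
        raise ValueError(f"need at least period+1 = {P + 1} weeks")
    seas = _seasonal_init(seasonal_init, P, 1.0)
    if np.any(seas <= 0):
        raise ValueError("multiplicative seasonal factors must be positive")
    a, b = _holt_init(y / np.resize(seas, len(y)), params, init, level_init, trend_init, init_m)
    fitted = np.full(len(y), np.nan)
    for i in range(1, len(y)):
        ph = i % P
        fitted[i] = (a + b) * seas[ph]
        a_new = al * (y[i] / seas[ph]) + (1 - al) * (a + b)
        b = be * (a_new - a) + (1 - be) * b
        seas[ph] = ga * (y[i] / a_new) + (1 - ga) * seas[ph]
        a = a_new
    ks = np.arange(1, params.horizon + 1)
    future = (a + ks * b) * seas[(len(y) + ks - 1) % P]
    return _trace(
        series, "hw_multiplicative", fitted, future,
        {"level": a, "trend": b, "seasonal": seas},
    )


def fit_double_exp(
    series: WeeklySeries,
    params: SmoothingParams | None = None,
    s_primary_init: float | None = None,
    s_secondary_init: float | None = None,
) -> ForecastTrace:
    """Two-pass (Brown-style) double exponential smoothing.

    The series is smoothed twice with separate weights alpha and gamma:
    ``S1[t] = alpha*Y[t] + (1-alpha)*S1[t-1]`` and
    ``S2[t] = gamma*S1[t] + (1-gamma)*S2[t-1]``; the forecast is
    ``level + k*trend`` with ``level = 2*S1 - S2`` and
    ``trend = (alpha/(1-alpha)) * (S1 - S2)``.  With gamma == alpha this is
    exactly Brown's classical double smoothing.  Both smoothed series start
    at the first observation unless explicit starts are supplied.
    """
    y = _require_complete(series)
    if len(y) < 2:
        raise ValueError("double exponential smoothing needs at least 2 weeks")
    params = params or SmoothingParams(alpha=0.2, gamma=0.15)
    al, ga = params.alpha, params.gamma
    if al == 1.0:
        raise ValueError("alpha == 1 degenerates the trend term (division by 1-alpha)")
    s1 = y[0] if s_primary_init is None else float(s_primary_init)
    s2 = s1 if s_secondary_init is None else float(s_secondary_init)
    fitted = np.full(len(y), np.nan)
    coef = al / (1 - al)
    for i in range(1, len(y)):
        fitted[i] = (2 * s1 - s2) + coef * (s1 - s2)
        s1 = al * y[i] + (1 - al) * s1
        s2 = ga * s1 + (1 - ga) * s2
    level = 2 * s1 - s2
    trend = coef * (s1 - s2)
    future = level + np.arange(1, params.horizon + 1) * trend
    return _trace(series, "double_exp", fitted, future, {"level": level, "trend": trend})


def demand_driven_forecast(
    patients_forecast: float, penetration: float, avg_quantity: float
) -> float:
    """Demand-driven sales forecast: patients x drug penetration x avg quantity.

    ``penetration`` is the fraction of prescribed patients who actually buy
    the drug, in [0, 1].
    """
    for name, v in (
        ("patients_forecast", patients_forecast),
        ("penetration", penetration),
        ("avg_quantity", avg_quantity),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if penetration > 1:
        raise ValueError(f"penetration must be <= 1, got {penetration}")
    return patients_forecast * penetration * avg_quantity


#: registry of the eight methods, in canonical order (used for tie-breaking)
METHODS = {
    "naive": fit_naive,
    "moving_average": fit_moving_average,
    "ses": fit_ses,
    "double_exp": fit_double_exp,
    "holt_linear": fit_holt_linear,
    "hw_no_trend": fit_hw_no_trend,
    "hw_additive": fit_hw_additive,
    "hw_multiplicative": fit_hw_multiplicative,
}

#: default smoothing settings per method
DEFAULT_PARAMS = {
    "naive": SmoothingParams(),
    "moving_average": SmoothingParams(window=2),
    "ses": SmoothingParams(alpha=0.2),
    "double_exp": SmoothingParams(alpha=0.2, gamma=0.15),
    "holt_linear": SmoothingParams(alpha=0.4, beta=0.7),
    "hw_no_trend": SmoothingParams(alpha=0.2, gamma=0.05),
    "hw_additive": SmoothingParams(alpha=0.2, beta=0.15, gamma=0.05),
    "hw_multiplicative": SmoothingParams(alpha=0.2, beta=0.15, gamma=0.05),
}


def fit_method(
    name: str, series: WeeklySeries, params: SmoothingParams | None = None, **kwargs
) -> ForecastTrace:
    """Fit a registered method by name with its default parameters."""
    if name not in METHODS:
        raise KeyError(f"unknown method {name!r}; choose from {list(METHODS)}")
    if params is None:
        params = DEFAULT_PARAMS[name]
    return METHODS[name](series, params, **kwargs)
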