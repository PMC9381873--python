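"""Forecast-accuracy metrics: MAPE, MSE and the U2 ratio.

Each method is scored only on the weeks where it produces a forecast, so the
denominators differ by warm-up (in a 13-week panel: 12 weeks for naive and
the exponential smoothers, 11 for a window-2 moving average).  The U2
statistic here is the *ratio of MSEs* against the naive benchmark — not the
square-rooted textbook form — so U2 < 1 means the method beats the naive
forecast and the naive method scores exactly 1 against itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import DEFAULT_SENTINEL_EPSILON, ForecastTrace, WeeklySeries

__all__ = ["AccuracyReport", "mape", "mse", "theil_u2", "evaluate", "accuracy_table"]


@dataclass
class AccuracyReport:
    """MAPE (%), MSE and U2 for one method on one series."""

    method_name: str
    mape: float
    mse: float
    u2: float
    n_forecasts: int

    def rounded(self) -> dict:
        """Display rounding: MAPE 2 d.p., MSE integer, U2 5 d.p."""
        return {
            "method": self.method_name,
            "MAPE": round(self.mape, 2),
            "MSE": round(self.mse),
            "U2": round(self.u2, 5),
            "n": self.n_forecasts,
        }


def _evaluated(actuals, fitted):
    actuals = np.asarray(actuals, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if len(actuals) != len(fitted):
        raise ValueError("actuals and fitted must have equal length")
    mask = ~np.isnan(fitted)
    if not mask.any():
        raise ValueError("no evaluated weeks: fitted is undefined everywhere")
    return actuals[mask], fitted[mask]


def mape(actuals, fitted, allow_sentinel: bool = False) -> float:
    """Mean absolute percentage error over the weeks where fitted is defined.

    Each week's error is scaled by that week's actual.  Actuals at or below
    the shortage-sentinel threshold explode the percentage (dividing by
    0.0001) and are rejected unless ``allow_sentinel=True``; true zeros are
    always an error.
    """
    a, f = _evaluated(actuals, fitted)
    if np.any(a == 0):
        raise ValueError("actual value of 0 on an evaluated week: MAPE undefined")
    if not allow_sentinel and np.any(a <= DEFAULT_SENTINEL_EPSILON):
        raise ValueError(
            "sentinel-valued actual on an evaluated week; impute shortages first "
            "or pass allow_sentinel=True"
        )
    return float(np.mean(np.abs(a - f) / a) * 100.0)


def mse(actuals, fitted) -> float:
    """Mean squared error over the weeks where fitted is defined."""
    a, f = _evaluated(actuals, fitted)
    return float(np.mean((a - f) ** 2))


def theil_u2(mse_method: float, mse_naive: float) -> float:
    """U2 ratio MSE(method) / MSE(naive); < 1 means the method beats naive."""
    if mse_naive == 0:
        raise ValueError("naive MSE is zero: U2 undefined")
    return float(mse_method / mse_naive)


def evaluate(
    series: WeeklySeries,
    trace: ForecastTrace,
    naive_trace: ForecastTrace,
    allow_sentinel: bool = False,
) -> AccuracyReport:
    """Score one method's trace against the series, benchmarked on naive.

    Each trace is evaluated on its own defined weeks (warm-ups differ), and
    U2 compares the method's MSE with the naive MSE over naive's weeks.
    """
    for t in (trace, naive_trace):
        if len(t.fitted) != series.n_weeks:
            raise ValueError(
                f"trace {t.method_name!r} length {len(t.fitted)} does not match "
                f"series length {series.n_weeks}"
            )
    m = mse(series.values, trace.fitted)
    m_naive = mse(series.values, naive_trace.fitted)
    return AccuracyReport(
        method_name=trace.method_name,
        mape=mape(series.values, trace.fitted, allow_sentinel=allow_sentinel),
        mse=m,
        u2=theil_u2(m, m_naive),
        n_forecasts=trace.n_defined,
    )


def accuracy_table(reports: list[AccuracyReport], rounded: bool = True) -> pd.DataFrame:
    """Accuracy rows (MAPE / MSE / U2) with one column per method."""
    df = pd.DataFrame(
        {
            r.method_name: (
                [round(r.mape, 2), round(r.mse), round(r.u2, 5)]
                if rounded
                else [r.mape, r.mse, r.u2]
            )
            for r in reports
        },
        index=["MAPE", "MSE", "U2"],
    )
    return df
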