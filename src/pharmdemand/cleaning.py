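"""Shortage-week imputation and Grubbs-test outlier handling.

The pipeline order is fixed: shortage weeks must be imputed before outlier
detection (a sentinel-valued week would otherwise dominate the Grubbs
statistic), and :func:`detect_outlier` enforces this by refusing series with
missing weeks.

Imputation replaces each shortage week with the arithmetic mean of the
observed weeks, which preserves the series mean exactly and shrinks the
sample standard deviation by sqrt((n_obs - 1) / (N - 1)).

The Grubbs test flags at most one extreme point per pass: the observation
with the largest standardised deviation |Y - mean| / s (sample s, divisor
N-1) is an outlier when G exceeds the critical value derived from Student's
t.  A flagged point is winsorised to mean +/- 3 s, with mean and s computed
excluding the point, so the week stays in the series but no longer distorts
downstream demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import WeeklySeries

__all__ = [
    "OutlierReport",
    "CleaningReport",
    "impute_missing",
    "grubbs_statistic",
    "grubbs_critical",
    "detect_outlier",
    "replace_outlier",
    "clean_series",
]

DEFAULT_ALPHA = 0.05


@dataclass
class OutlierReport:
    """Grubbs-test decision for one series."""

    series_id: str
    G: float
    G_crit: float
    candidate_week: int
    candidate_value: float
    is_outlier: bool
    replacement_value: float | None = None


@dataclass
class CleaningReport:
    """Audit trail of imputations and outlier replacements."""

    imputed_weeks: list = field(default_factory=list)  # (series_id, week, value)
    mean_used: dict = field(default_factory=dict)  # series_id -> mean
    outliers: list = field(default_factory=list)  # OutlierReport entries

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        self.imputed_weeks.extend(other.imputed_weeks)
        self.mean_used.update(other.mean_used)
        self.outliers.extend(other.outliers)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Long audit table: one row per modified point."""
        rows = [
            {
                "series_id": sid,
                "week": wk,
                "original": None,
                "replaced_with": val,
                "reason": "imputed_missing",
            }
            for sid, wk, val in self.imputed_weeks
        ]
        rows += [
            {
                "series_id": r.series_id,
                "week": r.candidate_week,
                "original": r.candidate_value,
                "replaced_with": r.replacement_value,
                "reason": "outlier_3s",
            }
            for r in self.outliers
            if r.is_outlier and r.replacement_value is not None
        ]
        return pd.DataFrame(
            rows, columns=["series_id", "week", "original", "replaced_with", "reason"]
        )


def impute_missing(series: WeeklySeries) -> tuple[WeeklySeries, CleaningReport]:
    """Replace every shortage week with the mean of the observed weeks."""
    report = CleaningReport()
    if not series.has_missing:
        return series, report
    obs = series.observed_values()
    if obs.size == 0:
        raise ValueError(f"series {series.series_id!r}: every week is missing")
    mean = float(obs.mean())
    values = series.values.copy()
    for wk in series.weeks[series.missing_mask]:
        values[wk - 1] = mean
        report.imputed_weeks.append((series.series_id, int(wk), mean))
    report.mean_used[series.series_id] = mean
    return series.with_values(values), report


def grubbs_statistic(values) -> tuple[float, int, float]:
    """Grubbs G = max |Y_i - mean| / s and its candidate point.

    Returns ``(G, candidate_week, candidate_value)`` with the week 1-based.
    Ties go to the earliest week.  Uses the sample standard deviation
    (divisor N-1).
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    s = y.std(ddof=1)
    if s == 0:
        raise ValueError("zero sample standard deviation: no outlier test possible")
    dev = np.abs(y - y.mean())
    idx = int(np.argmax(dev))  # argmax returns the first maximum -> earliest week
    return float(dev[idx] / s), idx + 1, float(y[idx])


def grubbs_critical(N: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Two-sided Grubbs critical value for sample size N at level alpha.

    ``G_crit = ((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2))`` where t is the upper
    alpha/(2N) quantile of Student's t with N-2 degrees of freedom.
    """
    if N < 3:
        raise ValueError("Grubbs critical value requires N >= 3")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    t = stats.t.ppf(1 - alpha / (2 * N), N - 2)
    return (N - 1) / np.sqrt(N) * np.sqrt(t**2 / (N - 2 + t**2))


def detect_outlier(series: WeeklySeries, alpha: float = DEFAULT_ALPHA) -> OutlierReport:
    """Single-pass two-sided Grubbs test on a fully observed series.

    The point is declared an outlier when G > G_crit.  Raises if the series
    still contains shortage weeks: imputation is a mandatory step before
    outlier detection.
    """
    if series.has_missing:
        raise ValueError(
            f"series {series.series_id!r} has shortage weeks; imputation is a "
            "mandatory step before outlier detection"
        )
    G, week, value = grubbs_statistic(series.values)
    G_crit = grubbs_critical(series.n_weeks, alpha)
    return OutlierReport(
        series_id=series.series_id,
        G=G,
        G_crit=float(G_crit),
        candidate_week=week,
        candidate_value=value,
        is_outlier=bool(G > G_crit),
    )


def replace_outlier(
    series: WeeklySeries,
    report: OutlierReport,
    policy: str = "mean_plus_3s",
) -> WeeklySeries:
    """Winsorise the flagged point and record the replacement in the report.

    ``mean_plus_3s`` (default) replaces the outlier with mean +/- 3 sample
    standard deviations — toward the mean on the outlier's side — with mean
    and s computed *excluding* the outlier.  ``series_mean`` replaces it with
    that leave-one-out mean.
    """
    if not report.is_outlier:
        raise ValueError("replace_outlier called on a non-outlier report")
    i = report.candidate_week - 1
    rest = np.delete(series.values, i)
    mean, s = rest.mean(), rest.std(ddof=1)
    if policy == "mean_plus_3s":
        sign = 1.0 if series.values[i] >= mean else -1.0
        new = mean + sign * 3.0 * s
    elif policy == "series_mean":
        new = mean
    else:
        raise ValueError(f"unknown replacement policy {policy!r}")
    values = series.values.copy()
    values[i] = new
    report.replacement_value = float(new)
    return series.with_values(values)


def clean_series(
    series: WeeklySeries,
    alpha: float = DEFAULT_ALPHA,
    policy: str = "mean_plus_3s",
    iterate: bool = False,
) -> tuple[WeeklySeries, CleaningReport]:
    """Full cleaning pass: impute shortages, then Grubbs-test and winsorise.

    By default at most one outlier is replaced per series; with
    ``iterate=True`` the test is re-run after each replacement until no
    outlier remains.
    """
    cleaned, report = impute_missing(series)
    while True:
        try:
            out = detect_outlier(cleaned, alpha)
        except ValueError:
            break  # zero variance after cleaning: nothing to test
        report.outliers.append(out)
        if not out.is_outlier:
            break
        cleaned = replace_outlier(cleaned, out, policy)
        if not iterate:
            break
    return cleaned, report
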