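"""Core containers for weekly pharmacy sales data.

Weeks are 1-based consecutive integers ``1..t`` throughout the package, so
that week indices printed in reports line up with the planning tables
pharmacists actually read.  A *shortage week* is a week in which the drug was
unavailable: the raw file records it as 0 (or a small sentinel such as
0.0001) rather than as true zero demand, and the containers keep the raw
value while flagging the week in ``missing_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: any quantity <= this is treated as a shortage sentinel by default
DEFAULT_SENTINEL_EPSILON = 0.001


class PanelError(ValueError):
    """Raised for structurally invalid panels or series."""


@dataclass
class WeeklySeries:
    """One pharmacy's (or the whole chain's) ordered weekly sales quantities.

    Parameters
    ----------
    series_id : str
        Pharmacy identifier, or ``"chain"`` for the aggregate.
    weeks : ndarray of int
        Consecutive 1-based week indices ``1..t``.
    values : ndarray of float
        Non-negative sales quantities (units sold per week).  Shortage
        sentinels are kept verbatim for audit.
    missing_mask : ndarray of bool
        True where the recorded value is a shortage sentinel.
    """

    series_id: str
    weeks: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.weeks)
        if not (len(self.values) == n == len(self.missing_mask)):
            raise PanelError(
                f"series {self.series_id!r}: weeks/values/mask lengths differ"
            )
        if n == 0:
            raise PanelError(f"series {self.series_id!r}: empty series")
        if self.weeks[0] != 1 or np.any(np.diff(self.weeks) != 1):
            bad = self.weeks.tolist()
            raise PanelError(
                f"series {self.series_id!r}: weeks must be consecutive from 1, got {bad}"
            )
        neg = np.flatnonzero(self.values < 0)
        if neg.size:
            raise PanelError(
                f"series {self.series_id!r}: negative quantity at week {self.weeks[neg[0]]}"
            )

    @classmethod
    def from_values(
        cls,
        series_id: str,
        values: Sequence[float],
        sentinel_epsilon: float = DEFAULT_SENTINEL_EPSILON,
    ) -> "WeeklySeries":
        """Build a series from raw quantities, flagging shortage sentinels."""
        values = np.asarray(values, dtype=float)
        weeks = np.arange(1, len(values) + 1)
        mask = values <= sentinel_epsilon
        return cls(series_id, weeks, values, mask)

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def observed_values(self) -> np.ndarray:
        """Values of the non-shortage weeks."""
        return self.values[~self.missing_mask]

    def with_values(self, values: np.ndarray, missing_mask=None) -> "WeeklySeries":
        mask = (
            np.zeros(len(self.weeks), dtype=bool)
            if missing_mask is None
            else np.asarray(missing_mask, dtype=bool)
        )
        return replace(self, values=np.asarray(values, dtype=float), missing_mask=mask)

    def drop_mask(self) -> "WeeklySeries":
        """Treat sentinel values as ordinary data (clears the shortage flags)."""
        return self.with_values(self.values)


@dataclass
class ChainPanel:
    """A pharmacy chain: per-pharmacy weekly series on a shared week index."""

    pharmacies: list[WeeklySeries]

    def __post_init__(self) -> None:
        if not self.pharmacies:
            raise PanelError("panel has no series")
        ref = self.pharmacies[0].weeks
        for s in self.pharmacies[1:]:
            if len(s.weeks) != len(ref) or np.any(s.weeks != ref):
                raise PanelError(
                    f"series {s.series_id!r} does not share the panel week range "
                    f"1..{ref[-1]}"
                )

    @property
    def n(self) -> int:
        """Number of pharmacies."""
        return len(self.pharmacies)

    @property
    def weeks(self) -> np.ndarray:
        return self.pharmacies[0].weeks

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    def __iter__(self):
        return iter(self.pharmacies)

    def to_records(self) -> list[tuple[str, int, float]]:
        """Flatten to long-format ``(series_id, week, quantity)`` records."""
        out: list[tuple[str, int, float]] = []
        for s in self.pharmacies:
            out.extend(zip([s.series_id] * s.n_weeks, s.weeks.tolist(), s.values.tolist()))
        return out


@dataclass
class SmoothingParams:
    """Smoothing weights and structural settings for the forecasting methods.

    alpha, beta, gamma are the level, trend and seasonal smoothing weights,
    each in [0, 1].  ``window`` is the moving-average interval, ``period`` the
    seasonal period P, ``horizon`` the forecast lead.
    """

    alpha: float = 0.2
    beta: float = 0.15
    gamma: float = 0.05
    window: int = 2
    period: int = 1
    horizon: int = 1

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("window", "period", "horizon"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name}={v} must be a positive integer")


@dataclass
class ForecastTrace:
    """One method's one-step-ahead fitted forecasts plus future forecasts.

    ``fitted`` is aligned with the series weeks and holds NaN on the method's
    warm-up weeks (weeks for which no forecast can be made).  ``future`` holds
    the forecasts for weeks ``t+1 .. t+horizon``.  ``components`` carries the
    final smoothing state (level, trend, seasonal factors) where applicable.
    """

    method_name: str
    weeks: np.ndarray
    fitted: np.ndarray
    future: np.ndarray
    components: dict = field(default_factory=dict)

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.fitted)

    @property
    def n_defined(self) -> int:
        return int(self.defined_mask.sum())


def build_panel(
    records: Iterable[tuple[str, int, float]],
    sentinel_epsilon: float = DEFAULT_SENTINEL_EPSILON,
) -> ChainPanel:
    """Assemble a validated :class:`ChainPanel` from long-format records.

    Records are ``(series_id, week, quantity)`` triples.  Quantities at or
    below ``sentinel_epsilon`` are flagged as shortage weeks (the raw value is
    preserved).  Raises :class:`PanelError` on non-consecutive weeks, ragged
    panels or negative quantities, naming the offending series and week.
    """
    by_series: dict[str, list[tuple[int, float]]] = {}
    for sid, week, qty in records:
        by_series.setdefault(str(sid), []).append((int(week), float(qty)))
    if not by_series:
        raise PanelError("no records")
    series = []
    for sid, rows in by_series.items():
        rows.sort(key=lambda r: r[0])
        weeks = np.array([w for w, _ in rows])
        vals = np.array([q for _, q in rows])
        if len(set(weeks.tolist())) != len(weeks):
            raise PanelError(f"series {sid!r}: duplicate week index")
        mask = vals <= sentinel_epsilon
        series.append(WeeklySeries(sid, weeks, vals, mask))
    return ChainPanel(series)


def aggregate_chain(
    panel: ChainPanel,
    series_id: str = "chain",
    missing_rule: str = "all",
) -> WeeklySeries:
    """Sum the panel week-wise into a single chain-level series.

    The raw values are summed as recorded, shortage sentinels included, so a
    chain-wide shortage week sums to ``n * sentinel`` (tiny but non-zero).
    ``missing_rule`` controls when an aggregate week is flagged missing:
    ``"all"`` (default) flags it only if *every* pharmacy is in shortage that
    week; ``"any"`` flags it if any is.
    """
    if missing_rule not in ("all", "any"):
        raise ValueError(f"unknown missing_rule {missing_rule!r}")
    values = np.sum([s.values for s in panel.pharmacies], axis=0)
    masks = np.array([s.missing_mask for s in panel.pharmacies])
    mask = masks.all(axis=0) if missing_rule == "all" else masks.any(axis=0)
    return WeeklySeries(series_id, panel.weeks.copy(), values, mask)


# ---------------------------------------------------------------- file I/O

CSV_COLUMNS = ["pharmacy_id", "week", "quantity"]


def read_long_csv(path, sentinel_epsilon: float = DEFAULT_SENTINEL_EPSILON) -> ChainPanel:
    """Read a long-format sales CSV (``pharmacy_id,week,quantity``).

    Decimal commas (e.g. ``0,0001``) are normalised to decimal points.
    """
    df = pd.read_csv(path, dtype={"pharmacy_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing column(s) {missing}; expected {CSV_COLUMNS}")
    qty = df["quantity"]
    if qty.dtype == object:
        qty = qty.astype(str).str.replace(",", ".", regex=False).astype(float)
    records = zip(df["pharmacy_id"], df["week"].astype(int), qty.astype(float))
    return build_panel(records, sentinel_epsilon=sentinel_epsilon)


def write_long_csv(panel: ChainPanel, path) -> None:
    df = pd.DataFrame(panel.to_records(), columns=CSV_COLUMNS)
    df.to_csv(path, index=False)
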