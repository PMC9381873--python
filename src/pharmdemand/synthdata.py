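"""Synthetic pharmacy-chain panels with the structure the model assumes.

Weekly demand per pharmacy is drawn from a normal distribution truncated at
zero (resampled, not clipped, so no artificial point mass at 0 masquerades
as a shortage).  Shortage runs set the requested weeks to the sentinel
value; a panic-buying outlier adds a single spike at ``mean + k * std``.
Pharmacies are generated independently — real panic buying plausibly
correlates them, which this generator does not model.

Two packaged fixtures reproduce the worked 13-week chain series (one
product without shortage, one with two shortage weeks and a recovery week)
so the whole pipeline can be exercised against printed numbers without any
download.  ``table9_specs()`` provides the eight per-pharmacy summary
parameters of the shortage product as generator specs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .timeseries import ChainPanel, WeeklySeries

__all__ = [
    "PharmacySpec",
    "generate_pharmacy",
    "generate_chain",
    "table_fixtures",
    "table9_specs",
    "SHORTAGE_SENTINEL",
]

SHORTAGE_SENTINEL = 0.0001

#: 13-week chain series for the product without supply shortage
_CHAIN_NO_SHORTAGE = [
    21819, 22344, 20675, 22695, 18226, 19217, 17944,
    17799, 18986, 24854, 16402, 18272, 19393,
]

#: 13-week chain series for the product with a shortage (weeks 8-9) and a
#: panic-recovery week 10
_CHAIN_SHORTAGE = [
    3037, 2910, 2751, 2799, 2375, 2469, 2530,
    SHORTAGE_SENTINEL, SHORTAGE_SENTINEL, 10, 1794, 1449, 1846,
]

#: before-treatment per-pharmacy summary statistics of the shortage product:
#: (series_id, mean, sample std, shortage weeks)
_TABLE9_BEFORE = [
    ("Pharma1", 296.0, 82.99, (8, 9, 10)),
    ("Pharma2", 318.4, 64.48, (8, 9, 10)),
    ("Pharma3", 306.1, 93.01, (8, 9, 10)),
    ("Pharma4", 320.1, 54.66, (8, 9, 10)),
    ("Pharma5", 286.1, 77.71, (8, 9, 10)),
    ("Pharma6", 286.4, 81.51, (8, 9, 10)),
    ("Pharma7", 309.4, 59.42, (8, 9, 10)),
    ("Pharma8", 248.7, 128.12, (8, 9)),
]


@dataclass
class PharmacySpec:
    """Generator parameters for one pharmacy's weekly series.

    ``outlier`` injects a single panic-buying spike: a ``(week, multiplier)``
    pair placing the value at ``mean + multiplier * std``.
    """

    series_id: str
    mean: float
    std: float
    weeks: int = 13
    shortage_weeks: tuple = field(default_factory=tuple)
    outlier: tuple | None = None  # (week, multiplier in std units)

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError(f"{self.series_id}: std must be >= 0")
        if self.weeks < 1:
            raise ValueError(f"{self.series_id}: weeks must be >= 1")
        bad = [w for w in self.shortage_weeks if not 1 <= w <= self.weeks]
        if bad:
            raise ValueError(f"{self.series_id}: shortage weeks {bad} out of range")
        if self.outlier is not None:
            wk = self.outlier[0]
            if not 1 <= wk <= self.weeks:
                raise ValueError(f"{self.series_id}: outlier week {wk} out of range")
            if wk in self.shortage_weeks:
                raise ValueError(
                    f"{self.series_id}: outlier week {wk} collides with a shortage week"
                )


def _truncated_normal(rng, mean, std, size):
    """Normal(mean, std) resampled until non-negative."""
    out = rng.normal(mean, std, size)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, std, int(neg.sum()))
    raise RuntimeError("truncated-normal resampling failed to converge")


def generate_pharmacy(spec: PharmacySpec, seed: int) -> WeeklySeries:
    """Draw one pharmacy's weekly series; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    values = _truncated_normal(rng, spec.mean, spec.std, spec.weeks)
    if spec.outlier is not None:
        wk, mult = spec.outlier
        values[wk - 1] = spec.mean + mult * spec.std
    for wk in spec.shortage_weeks:
        values[wk - 1] = SHORTAGE_SENTINEL
    weeks = np.arange(1, spec.weeks + 1)
    mask = np.zeros(spec.weeks, dtype=bool)
    mask[[w - 1 for w in spec.shortage_weeks]] = True
    return WeeklySeries(spec.series_id, weeks, values, mask)


def _series_seed(base_seed: int, series_id: str) -> int:
    """Stable per-series seed: adding a pharmacy never perturbs the others."""
    return (int(base_seed) + zlib.crc32(series_id.encode())) % (2**31)


def generate_chain(specs: list[PharmacySpec], seed: int) -> ChainPanel:
    """Generate a panel of independently drawn pharmacies."""
    if not specs:
        raise ValueError("no pharmacy specs")
    weeks = {s.weeks for s in specs}
    if len(weeks) != 1:
        raise ValueError(f"specs disagree on week count: {sorted(weeks)}")
    return ChainPanel(
        [generate_pharmacy(s, _series_seed(seed, s.series_id)) for s in specs]
    )


def table_fixtures() -> tuple[WeeklySeries, WeeklySeries]:
    """The two packaged 13-week chain series.

    Returns ``(no_shortage, shortage)``: the product with uninterrupted
    supply, and the product whose weeks 8-9 are shortage sentinels with a
    near-empty recovery week 10.
    """
    return (
        WeeklySeries.from_values("chain_no_shortage", _CHAIN_NO_SHORTAGE),
        WeeklySeries.from_values("chain_shortage", _CHAIN_SHORTAGE),
    )


def table9_specs(shortage: bool = True) -> list[PharmacySpec]:
    """Eight per-pharmacy generator specs calibrated to the shortage product.

    Means and standard deviations are the before-treatment summary values;
    with ``shortage=False`` the same demand parameters are used but no weeks
    are blanked out.
    """
    return [
        PharmacySpec(
            series_id=sid,
            mean=mean,
            std=std,
            weeks=13,
            shortage_weeks=weeks if shortage else (),
        )
        for sid, mean, std, weeks in _TABLE9_BEFORE
    ]
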