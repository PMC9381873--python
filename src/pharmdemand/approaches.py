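"""The four hierarchical planning approaches and accuracy-based selection.

The chain can be forecast at two planning levels, each with or without an
outlier response:

1. aggregate the pharmacies' sales, forecast the chain series as-is;
2. aggregate, impute shortage weeks, winsorise Grubbs outliers, forecast;
3. forecast every pharmacy separately and sum the per-week forecasts
   (shortage weeks are imputed per pharmacy first);
4. as 3, but each pharmacy is also Grubbs-tested and winsorised.

Every approach fits all (requested) methods, scores them with MAPE / MSE /
U2 against the aggregated actuals, and selects the method with the lowest
U2.  For recursions that are linear in the data with shared parameters and
initialisation (naive, single exponential smoothing, moving average),
summing per-pharmacy forecasts is algebraically identical to forecasting the
summed series, so approaches 1 and 3 coincide exactly for those methods — a
useful internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accuracy import AccuracyReport, evaluate
from .cleaning import DEFAULT_ALPHA, CleaningReport, clean_series, impute_missing
from .forecasters import DEFAULT_PARAMS, METHODS
from .timeseries import ChainPanel, ForecastTrace, SmoothingParams, WeeklySeries, aggregate_chain

__all__ = [
    "ApproachResult",
    "run_approach_1",
    "run_approach_2",
    "run_approach_3",
    "run_approach_4",
    "run_approach",
    "select_best",
    "safety_stock_uplift",
]


@dataclass
class ApproachResult:
    """Everything one approach produced for one panel."""

    approach_id: int
    per_method: dict  # method name -> AccuracyReport
    best_method: str
    cleaning: CleaningReport
    traces: dict  # method name -> chain-level ForecastTrace
    chain_actuals: WeeklySeries
    negative_forecast_methods: list = field(default_factory=list)

    @property
    def chain_forecast(self) -> ForecastTrace:
        """Chain-level trace of the selected best method."""
        return self.traces[self.best_method]

    @property
    def reports(self) -> list[AccuracyReport]:
        return list(self.per_method.values())


def select_best(reports) -> str:
    """Pick the method with the lowest U2; ties go to registry order.

    When no method beats the naive benchmark (every U2 >= 1) the naive
    method is returned: added complexity must earn its keep.
    """
    if hasattr(reports, "values"):
        reports = list(reports.values())
    if not reports:
        raise ValueError("no accuracy reports to select from")
    order = {name: i for i, name in enumerate(METHODS)}
    reports = sorted(reports, key=lambda r: order.get(r.method_name, len(order)))
    best = min(reports, key=lambda r: r.u2)  # min() keeps the first of ties
    if best.u2 >= 1.0:
        return "naive"
    return best.method_name


def safety_stock_uplift(forecast: float, growth_rate: float) -> float:
    """Uplift a forecast by a category growth rate to cover safety stock.

    For drug categories with growing sales (historical-data methods lag the
    rise), the forecast is scaled by ``1 + growth_rate``; published category
    rates run from 1% to 10%.
    """
    if growth_rate < 0:
        raise ValueError(f"growth_rate must be non-negative, got {growth_rate}")
    return forecast * (1.0 + growth_rate)


def _params_for(name: str, params_by_method) -> SmoothingParams:
    if params_by_method and name in params_by_method:
        return params_by_method[name]
    return DEFAULT_PARAMS[name]


def _method_names(methods) -> list[str]:
    if methods is None:
        return list(METHODS)
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise KeyError(f"unknown method(s) {unknown}; choose from {list(METHODS)}")
    # keep registry order regardless of request order
    return [m for m in METHODS if m in set(methods)]


def _fit_all(series: WeeklySeries, params_by_method, methods) -> dict:
    return {
        name: METHODS[name](series, _params_for(name, params_by_method))
        for name in _method_names(methods)
    }


def _evaluate_all(
    actuals: WeeklySeries, traces: dict, allow_sentinel: bool
) -> dict:
    naive_trace = traces["naive"]
    return {
        name: evaluate(actuals, tr, naive_trace, allow_sentinel=allow_sentinel)
        for name, tr in traces.items()
    }


def _finalize(approach_id, actuals, traces, cleaning, allow_sentinel=False) -> ApproachResult:
    per_method = _evaluate_all(actuals, traces, allow_sentinel)
    negative = [
        name
        for name, tr in traces.items()
        if np.nanmin(tr.fitted) < 0 or np.min(tr.future) < 0
    ]
    return ApproachResult(
        approach_id=approach_id,
        per_method=per_method,
        best_method=select_best(per_method),
        cleaning=cleaning,
        traces=traces,
        chain_actuals=actuals,
        negative_forecast_methods=negative,
    )


def run_approach_1(
    panel: ChainPanel, params_by_method=None, methods=None
) -> ApproachResult:
    """Aggregate the chain and forecast the summed series as recorded.

    Shortage sentinels are *kept* in the aggregate (the raw sums are what the
    chain's ledger shows), so on a shortage product the percentage errors
    around sentinel weeks explode — which is exactly why the cleaned
    approaches exist.
    """
    chain = aggregate_chain(panel).drop_mask()
    traces = _fit_all(chain, params_by_method, methods)
    return _finalize(1, chain, traces, CleaningReport(), allow_sentinel=True)


def run_approach_2(
    panel: ChainPanel,
    params_by_method=None,
    alpha: float = DEFAULT_ALPHA,
    methods=None,
    policy: str = "mean_plus_3s",
) -> ApproachResult:
    """Aggregate, then impute shortages and winsorise outliers before fitting."""
    chain = aggregate_chain(panel)
    cleaned, report = clean_series(chain, alpha=alpha, policy=policy)
    traces = _fit_all(cleaned, params_by_method, methods)
    return _finalize(2, cleaned, traces, report)


def _sum_traces(per_pharmacy: list[ForecastTrace], name: str) -> ForecastTrace:
    """Week-wise sum of per-pharmacy traces (warm-up weeks stay undefined)."""
    fitted = np.sum([t.fitted for t in per_pharmacy], axis=0)
    future = np.sum([t.future for t in per_pharmacy], axis=0)
    return ForecastTrace(
        method_name=name,
        weeks=per_pharmacy[0].weeks.copy(),
        fitted=fitted,
        future=future,
        components={"summed_over": len(per_pharmacy)},
    )


def _run_disaggregated(
    approach_id, panel, params_by_method, methods, cleaner, evaluate_on_cleaned
) -> ApproachResult:
    names = _method_names(methods)
    report = CleaningReport()
    cleaned_series = []
    for s in panel:
        cs, rep = cleaner(s)
        report.merge(rep)
        cleaned_series.append(cs)
    cleaned_panel = ChainPanel(cleaned_series)
    traces = {
        name: _sum_traces(
            [METHODS[name](s, _params_for(name, params_by_method)) for s in cleaned_panel],
            name,
        )
        for name in names
    }
    if evaluate_on_cleaned:
        actuals = aggregate_chain(cleaned_panel)
        allow_sentinel = False
    else:
        actuals = aggregate_chain(panel).drop_mask()
        allow_sentinel = True
    return _finalize(approach_id, actuals, traces, report, allow_sentinel)


def run_approach_3(
    panel: ChainPanel,
    params_by_method=None,
    methods=None,
    evaluate_on_cleaned: bool = False,
) -> ApproachResult:
    """Forecast each pharmacy, sum the forecasts, score at chain level.

    Per-pharmacy shortage weeks are imputed (a mandatory step before any
    smoother runs); no outlier response.  By default the summed forecasts are
    judged against the aggregate of the *original* actuals so U2 measures
    real predictive quality; ``evaluate_on_cleaned=True`` scores against the
    imputed aggregate instead.
    """
    return _run_disaggregated(
        3, panel, params_by_method, methods, impute_missing, evaluate_on_cleaned
    )


def run_approach_4(
    panel: ChainPanel,
    params_by_method=None,
    alpha: float = DEFAULT_ALPHA,
    methods=None,
    policy: str = "mean_plus_3s",
    evaluate_on_cleaned: bool = False,
) -> ApproachResult:
    """As approach 3, but each pharmacy is Grubbs-tested and winsorised too."""
    return _run_disaggregated(
        4,
        panel,
        params_by_method,
        methods,
        lambda s: clean_series(s, alpha=alpha, policy=policy),
        evaluate_on_cleaned,
    )


def run_approach(approach_id: int, panel: ChainPanel, **kwargs) -> ApproachResult:
    """Dispatch to one of the four approaches by number."""
    runners = {1: run_approach_1, 2: run_approach_2, 3: run_approach_3, 4: run_approach_4}
    if approach_id not in runners:
        raise ValueError(f"approach must be 1..4, got {approach_id}")
    return runners[approach_id](panel, **kwargs)
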