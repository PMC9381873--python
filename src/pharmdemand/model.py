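"""High-level modelling interface: a model built from panel data whose
``fit`` returns a results object with accuracy tables and a summary.

This is the front door for interactive use::

    model = DemandPlanningModel.from_dataframe(df)     # pharmacy_id, week, quantity
    res = model.fit(approach="all")
    print(res.summary())
    res.forecast(horizon=1)

The heavy lifting lives in :mod:`pharmdemand.approaches`; this layer only
packages panels, runs the requested approaches and renders results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accuracy import accuracy_table
from .approaches import ApproachResult, run_approach
from .cleaning import DEFAULT_ALPHA
from .timeseries import ChainPanel, WeeklySeries, build_panel, read_long_csv

__all__ = ["DemandPlanningModel", "DemandPlanningResults"]


class DemandPlanningModel:
    """Weekly drug-sales planning model for a pharmacy chain.

    Parameters
    ----------
    panel : ChainPanel
        Per-pharmacy weekly sales (shortage weeks flagged).
    params_by_method : dict, optional
        ``method name -> SmoothingParams`` overrides; unlisted methods use
        the standard defaults.
    methods : list of str, optional
        Subset of the eight registered methods to fit.
    alpha : float
        Significance level of the Grubbs outlier test (approaches 2 and 4).
    """

    def __init__(
        self,
        panel: ChainPanel,
        params_by_method=None,
        methods=None,
        alpha: float = DEFAULT_ALPHA,
    ):
        if isinstance(panel, WeeklySeries):
            panel = ChainPanel([panel])
        self.panel = panel
        self.params_by_method = params_by_method
        self.methods = methods
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DemandPlanningModel":
        """Build from a long-format frame with pharmacy_id/week/quantity columns."""
        records = zip(df["pharmacy_id"], df["week"], df["quantity"])
        return cls(build_panel(records), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DemandPlanningModel":
        return cls(read_long_csv(path), **kwargs)

    def fit(self, approach=1) -> "DemandPlanningResults":
        """Run one approach (1..4) or ``"all"`` and return the results."""
        ids = [1, 2, 3, 4] if approach == "all" else [int(approach)]
        results = {}
        for aid in ids:
            kwargs = {"params_by_method": self.params_by_method, "methods": self.methods}
            if aid in (2, 4):
                kwargs["alpha"] = self.alpha
            results[aid] = run_approach(aid, self.panel, **kwargs)
        return DemandPlanningResults(self, results)


class DemandPlanningResults:
    """Fitted accuracy tables, method selection and forecasts per approach."""

    def __init__(self, model: DemandPlanningModel, results: dict):
        self.model = model
        self.results = results  # approach id -> ApproachResult

    def __getitem__(self, approach_id: int) -> ApproachResult:
        return self.results[approach_id]

    @property
    def best_approach(self) -> int:
        """Approach whose selected method attains the lowest U2 overall."""
        def key(aid):
            res = self.results[aid]
            return res.per_method[res.best_method].u2
        return min(self.results, key=key)

    def accuracy_frame(self, rounded: bool = True) -> pd.DataFrame:
        """MAPE/MSE/U2 rows for every fitted approach, stacked."""
        frames = []
        for aid, res in self.results.items():
            df = accuracy_table(res.reports, rounded=rounded)
            df.index = pd.MultiIndex.from_product([[aid], df.index], names=["approach", "metric"])
            frames.append(df)
        return pd.concat(frames)

    def forecast(self, approach_id: int | None = None) -> np.ndarray:
        """Future chain-level forecast of the selected method."""
        aid = self.best_approach if approach_id is None else approach_id
        return self.results[aid].chain_forecast.future

    def summary(self) -> str:
        """Fixed-width report: accuracy per method and the selection per approach."""
        lines = ["Demand planning summary", "=" * 70]
        lines.append(f"panel: {self.model.panel.n} pharmacies x {self.model.panel.n_weeks} weeks")
        for aid, res in sorted(self.results.items()):
            lines.append("")
            lines.append(f"Approach {aid}")
            lines.append("-" * 70)
            display = pd.DataFrame(
                {
                    r.method_name: [f"{r.mape:.2f}", f"{r.mse:.0f}", f"{r.u2:.5f}"]
                    for r in res.reports
                },
                index=["MAPE", "MSE", "U2"],
            )
            lines.append(display.to_string())
            best = res.best_method
            u2 = res.per_method[best].u2
            lines.append(f"selected method: {best} (U2 = {u2:.5f})")
            n_imp = len(res.cleaning.imputed_weeks)
            n_out = sum(1 for o in res.cleaning.outliers if o.is_outlier)
            if n_imp or n_out:
                lines.append(f"cleaning: {n_imp} week(s) imputed, {n_out} outlier(s) winsorised")
            if res.negative_forecast_methods:
                lines.append(
                    "warning: negative forecasts from "
                    + ", ".join(res.negative_forecast_methods)
                )
        lines.append("")
        lines.append(f"best approach overall: {self.best_approach}")
        return "\n".join(lines)
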