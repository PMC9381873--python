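# Methods

## The problem and the model

A pharmacy chain of *n* outlets records weekly unit sales `Y_i(t)` per
pharmacy, `t = 1..T` (weeks are abstract 1-based indices; the reference
panel is n = 8, T = 13).  Forecasts can be produced at the **aggregate**
level — forecast the chain sum `Y(t) = Σ_i Y_i(t)` — or at the
**disaggregate** level — forecast each pharmacy and sum the forecasts
`Ŷ(t+τ) = Σ_i Ŷ_i(t+τ)`.  Crossing this choice with an optional cleaning
step (shortage imputation + outlier winsorisation) gives the four planning
approaches the package implements.  A method is selected per approach by
the U2 ratio below; the horizon is τ = 1 throughout the standard pipeline
(one-step-ahead planning), though every forecaster accepts a longer
horizon.

## Forecasting methods

All eight are recursions of the exponential-smoothing family, run with
*fixed* smoothing weights (no likelihood optimisation — the point is a
stable, auditable planning rule, and the weights are part of the run
configuration):

| method | defaults |
|---|---|
| naive | — |
| moving average | window 2 |
| SES | α = 0.2 |
| double smoothing | α = 0.2, γ = 0.15 |
| Holt linear | α = 0.4, β = 0.7 |
| HW no trend | α = 0.2, γ = 0.05 |
| HW additive | α = 0.2, β = 0.15, γ = 0.05 |
| HW multiplicative | α = 0.2, β = 0.15, γ = 0.05 |

Conventions that matter for reproducibility:

* **Warm-up.**  `fitted[w]` is the forecast of week *w* made at *w−1*.  It
  is undefined (NaN) for week 1 for every recursion, and for weeks `1..w`
  for a moving average of window *w*.  Accuracy metrics average only over
  defined weeks and record the count, so in a 13-week panel SES is scored
  on 12 weeks and the window-2 moving average on 11.  No common evaluation
  window is forced — that asymmetry is deliberate and matches how the
  reference tables were computed.
* **SES initialisation** is `F(2) = Y(1)`; this choice exactly reproduces
  the reference chain-level SES column and accuracy row.
* **Holt-family initialisation** is a configuration choice
  (`ols_on_first_m`, default m = 2, i.e. the line through the first two
  observations; `first_observation`, i.e. level = Y(1), zero trend; or
  explicit values).  The state is defined *at week 1* and the recursion
  runs from week 2.  Published Holt-family table rows in the source
  material start from an unexplained initial forecast that no tested rule
  reproduces, so those rows are validated structurally instead: fixed-point
  exactness on linear/periodic series with exact initialisation, parameter
  degeneracies (β = 0 ⇒ SES; γ = 0 with neutral seasonals ⇒ Holt), and
  1e-9 agreement with an independent step-by-step re-implementation.
* **Seasonality.**  The seasonal period P defaults to 1 (the study window
  is 13 weekly points with no modelled seasonality); any P ≥ 1 is
  accepted.  Seasonal factors initialise to 0 (additive) / 1
  (multiplicative) unless supplied.  The multiplicative form requires
  strictly positive data and refuses sentinels.
* **Double smoothing** smooths the series twice with *distinct* weights
  (α then γ) and forecasts `level + k·trend` with `level = 2S′ − S″`,
  `trend = (α/(1−α))(S′ − S″)`.  Keeping the trend coefficient tied to the
  first-stage weight is a judgement call; with γ = α the method is exactly
  Brown's classical double smoothing, which the tests pin down.
* **Negative forecasts are returned as computed** (a trend crashed by a
  shortage run can legitimately go negative); approach results flag the
  affected methods rather than clipping, and an explicit floor is left to
  the caller.

## Accuracy metrics

* `MAPE = 100 · mean(|Y − Ŷ| / Y)` over evaluated weeks, each week scaled
  by its own actual.  Actuals of zero are an error; sentinel-valued actuals
  (≤ 0.001) are refused unless explicitly allowed, because dividing by
  0.0001 explodes the percentage — which is also exactly what happens, and
  is reported, when the uncleaned approach 1 runs on a shortage product.
* `MSE = mean((Y − Ŷ)²)` over evaluated weeks.
* `U2 = MSE(method) / MSE(naive)` — deliberately *not* the square-rooted
  textbook Theil statistic; the plain MSE ratio is what the selection rule
  uses and what the reference tables print.  U2 = 1 for naive against
  itself; U2 < 1 means the method earns its complexity.  A constant series
  makes the naive MSE zero and the ratio undefined; the pipeline raises
  rather than ranking methods on a degenerate benchmark.

## Cleaning

* **Imputation.**  Shortage weeks (value ≤ the sentinel epsilon, default
  0.001, covering both 0 and the 0.0001 convention; raw values are kept
  for audit) are replaced by the mean of the observed weeks.  This
  preserves the mean exactly and shrinks the sample std by
  `√((n_obs−1)/(N−1))` — e.g. 3 imputed weeks out of 13 shrink 82.99 to
  71.87.
* **Grubbs test** (two-sided, single outlier): `G = max|Y − Ȳ|/s` with the
  sample (N−1) std, compared with
  `G_crit = ((N−1)/√N)·√(t²/(N−2+t²))`, t the upper α/(2N) quantile of
  Student's t with N−2 d.f.; α defaults to 0.05, and G_crit(13, 0.05) =
  2.4620.  The decision rule is the standard one (G > G_crit ⇒ outlier);
  the source prose states the inverted rule, which contradicts its own
  worked tables, so the package follows the standard rule and exposes both
  G and G_crit for users who want any other rule.  Ties in the extreme
  deviation go to the earliest week.
* **Replacement** winsorises to `Ȳ ± 3s` on the outlier's side, with Ȳ and
  s computed *excluding* the flagged point (policy `mean_plus_3s`;
  `series_mean` is available).  One point per series per pass by default;
  an iterative mode re-tests after replacement.  Detection on a series with
  un-imputed weeks raises: imputation is a mandatory prior step.

## Approaches 3–4: evaluation target

Summed per-pharmacy forecasts are scored against the aggregate of the
**original** actuals by default, so U2 measures genuine predictive quality;
`evaluate_on_cleaned=True` scores against the imputed/winsorised aggregate
instead (closer to how the reference shortage-product tables appear to have
been computed).  For the linear recursions (naive, SES, moving average)
with shared parameters and initialisation, approach 3 is algebraically
identical to approach 1 — the suite uses this as a cross-module oracle.

## Synthetic data

The generator emulates the study panel: weekly demand per pharmacy drawn
i.i.d. from Normal(mean, std) truncated at zero by resampling (clipping
would create a point mass at 0 that masquerades as shortage), with
per-pharmacy means/stds defaulting to the reference panel's summary
statistics (≈ 250–320 units/week, std ≈ 55–128), optional shortage runs
(the packaged pattern: weeks 8–10 for seven pharmacies, 8–9 for the
eighth) and a single panic-buying spike at `mean + k·std`.  Per-series
seeds derive from the base seed plus a stable hash of the series id, so
adding a pharmacy never perturbs existing draws.

What the generator does **not** model: cross-pharmacy correlation (panic
buying plausibly correlates outlets; draws here are independent), demand
trend/seasonality beyond the flat normal regime, and the demand-suppression
dynamics around a recovery week.  Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the stated statistical
assumptions, not performance on real correlated retail data.

## Problem sizes and determinism

The standard test and validation runs use the 13-week fixtures, 8×13
synthetic panels, 50-series oracle sweeps, and 200–400 seeded replicates
for the detection-probability and parameter-recovery checks — comfortable
margins for the laws being tested while keeping runs quick.  Everything
random flows from explicit integer seeds; equal seed and inputs give
byte-identical CLI outputs.

## Known limitations

* Fixed smoothing weights: no parameter optimisation or model selection
  beyond the U2 rule.
* Single-product pipeline; no cross-product pooling or reconciliation
  beyond simple summation.
* The Grubbs test assumes approximate normality; with 13 points its power
  against moderate outliers is limited (a 6σ spike is caught essentially
  always; a 3σ one often is not).
* Safety-stock handling is a flat multiplicative uplift
  (`forecast × (1 + growth_rate)`), not a service-level calculation.
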