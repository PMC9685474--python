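# Methods

This note records the statistical methods implemented in `heatattr`,
the numerical choices behind them, and the design of the synthetic
generator used to validate the pipeline.

## 1. Data contract

A daily series is one CSV row per region-day: `date`, `region`,
`tmax_c`, `tmin_c`, `tmean_c`, `tdew_c`, `hri_count`, `population`.
Counts below five are withheld for confidentiality ("suppression") and
appear as an empty field or the sentinel `S`; `impute_suppressed`
replaces them with the fixed constant 3, the midpoint value
conventionally published for the suppressed range. Daily rates are
`count / population × 100,000`. Calendar covariates are day-of-week
(7 levels), weekend/weekday, month and year, all treated as
categorical.

Candidate heat metrics are screened by Spearman rank correlation with
the daily rate; metrics with ρ > 0.55 are retained. Rank correlation
is used because the exposure-response relation is monotone but not
linear.

## 2. Thermal indices

All indices take °C and return °C.

* **Saturation vapor pressure** (Magnus): `e_s(T) = 6.112 exp(17.67 T /
  (T + 243.5))` hPa; relative humidity is `100 e_s(T_d)/e_s(T)`,
  clamped to [0, 100].
* **Apparent temperature** (Steadman): `AT = T + 0.33 e − 4.00` with
  `e` the vapor pressure at the dew point.
* **NWS heat index**: the simple formula averaged with `T`; when that
  average reaches 80 °F, the Rothfusz regression with the published
  low-humidity (RH < 13%, 80–112 °F) and high-humidity (RH > 85%,
  80–87 °F) adjustments. Computed in °F internally.
* **Humidex**: `T + 0.5555 (e − 10)` with `e = 6.11 exp(5417.753
  (1/273.16 − 1/(273.15 + T_d)))`.
* **Thom discomfort index**: `T − 0.55 (1 − 0.01 RH)(T − 14.5)`; equals
  `T` at saturation and pivots at 14.5 °C.
* **Excess Heat Factor**: `EHI_sig = mean(T, 3 days) − T_95` (the
  series' own 95th percentile), `EHI_accl = mean(T, 3 days) −
  mean(T, previous 30 days)`, `EHF = EHI_sig × max(1, EHI_accl)`.
  The first 32 days have no 30-day history and are NaN.

Each index has an independent in-test oracle (hand transcription of the
published formula) in `tests/test_metrics.py`.

## 3. Exposure-response model (penalized GAM)

The daily rate (gamma family) or count (Poisson) is modeled with a log
link as

```
log μ_i = f(tmax_i) + Σ_k γ_k 1[covariate_ik]
```

where `f` is a natural cubic regression spline with 3–5 knots placed at
quantiles of the exposure.

**Basis.** The spline is parameterized by its values at the knots
(values-at-knots form). Second derivatives at the knots follow from
the natural-spline tridiagonal system `B m = D g`; the curvature
penalty is exact: `∫ f''(x)² dx = gᵀ Dᵀ B⁻¹ D g = gᵀ S g`. Outside the
boundary knots the spline continues linearly (C¹), and predictions
report how many points used the extension.

**Identifiability.** The values-at-knots basis is a partition of unity,
so after centering the columns are collinear with the intercept and `S`
annihilates the constant direction. The model drops the last centered
spline column and the corresponding row/column of `S` (a gauge choice;
the fitted smooth and the penalty value are invariant to it).
Categorical covariates use treatment coding with the first sorted level
as reference.

**Fitting.** Penalized IRLS: at each step solve `(XᵀWX + λS)β = XᵀWz`
with the usual log-link working response and weights (`W = diag(μ)` for
Poisson, identity for gamma deviance weights on the log scale).
Convergence tolerance 1e-8, at most 200 iterations. With λ = 0 and a
linear term this reduces exactly to an unpenalized GLM, which is tested
against an independent IRLS implementation.

**Penalty selection.** λ minimizes `GCV(λ) = n D(λ) / (n − edf(λ))²`
with `D` the family deviance and `edf = tr((XᵀWX + λS)⁻¹ XᵀWX)`. The
grid is deterministic (45 log-spaced points, 1e-4 to 1e7) with a
15-point refinement around the minimum, so the fit is reproducible.

**Model comparison.** `compare_models` ranks fits by AIC with
deviance-explained as tiebreak. For the gamma family the AIC uses the
full gamma log-likelihood with shape 1/φ (φ the Pearson dispersion) and
counts the dispersion as a parameter; a deviance/φ quasi-AIC would not
be comparable across models because each model's own dispersion
rescales its deviance.

## 4. Distributed-lag nonlinear model

The cross-basis over exposure `x` and lags 0..L (L = 5) is

```
cb[i, jK + k] = Σ_ℓ b_j(x_{i−ℓ}) c_k(ℓ)
```

with `b_j` the natural-spline exposure basis (5 equally spaced knots by
default) and `c_k` a lag basis: either a natural spline with knots
equally spaced on `log(1 + ℓ)` (default, 3 knots) or lag indicators
(unconstrained). The partition-of-unity redundancy is removed by
dropping the last exposure-basis block. Rows with incomplete lag
history (the first L days) are flagged and excluded from fitting.

The model is a Poisson GLM (statsmodels) of the daily count on the
cross-basis plus optional categorical covariates. Relative risks are
contrasts against a reference exposure — the 70th percentile of the
observed series by default:

```
log RR(x, ℓ) = Σ_jk (b_j(x) − b_j(x_ref)) c_k(ℓ) β_jk
```

Contrast vectors are orthogonal to the dropped null directions, so RR
is invariant to the gauge choice, and RR(x_ref, ℓ) = 1 exactly at
every lag. Confidence intervals are normal-theory on the log scale
(delta method).

## 5. Counterfactual attribution

Observed rates come from imputed counts; counterfactual rates are the
fitted model's predictions at the counterfactual temperatures *with the
factual calendar covariates* — only the exposure is substituted. The
daily attributable percent is `100 (observed − predicted_cf) /
predicted_cf`, summarized by pooled and per-year median and IQR. The
report adds a paired *t* test of observed vs counterfactual daily
rates, a chi-square test on the 2×2 table of hot-day (tmax ≥ 30 °C)
frequencies in the two temperature series, and the expected excess
visits per season: mean daily rate difference × population/100,000 ×
season length (152 days).

Medians, not means, summarize the daily percents: the ratio of a
Poisson count to a smooth prediction is heavily right-skewed. A known
small-sample artifact is that the *median* of such ratios sits slightly
below the mean even under the null (the median of a Poisson variable is
a little below its mean), giving a median attributable percent of
roughly −1% when the true effect is zero; the acceptance suite bounds
this at ±1 point.

## 6. Scenario projection

Projection uses a reduced, temperature-only model (no calendar
covariates, 3-knot spline): scenario temperature series carry no
calendar identity, and the reduced model prevents the projection from
depending on an arbitrary covariate assignment. For each
period × scenario × climate-model cell the projected daily rates are
summarized by median and IQR; scenarios are compared within period by
percent change of medians and a paired *t* test (series are aligned by
day), and periods are compared within scenario by one-way ANOVA.

## 7. Statistical tests

`paired_t`, `hot_day_chisq` (Pearson 2×2, continuity correction off by
default so the statistic matches the textbook formula) and
`one_way_anova` wrap scipy with explicit degenerate-case handling
(zero-variance differences, empty table margins). Each is tested
against a brute-force textbook computation to 1e-10.

## 8. Synthetic generator

The generator is a first-class component: it produces data whose
correct analysis is known in closed form.

* **Weather.** Within each May 1 – Sep 30 season, daily maximum
  temperature is a half-sine mean curve (base 27.5 °C, amplitude
  4.5 °C) plus stationary AR(1) noise (φ = 0.7, innovation sd 1.5 °C),
  restarted from the stationary distribution each season. Mean,
  minimum and dew point follow by fixed offsets (dew point with noise,
  capped at tmax).
* **Risk curve.** `log rate(t) = log(0.13) + 0.14 max(0, t − 22)`
  (rate per 100,000). Counts are Poisson with day-of-week multipliers
  (weekends +8% on the log scale); counts below 5 are withheld exactly
  as in the raw-data contract.
* **Counterfactual.** The factual series minus a warming offset
  (default 1.0 °C). Because the true curve is log-linear above the
  knee, the implied attributable percent is computable exactly from the
  drawn temperatures; at the defaults it is ≈ 15%, with roughly 30%
  more hot days in the factual series.
* **Scenarios.** Shifted copies of the factual series for 3 periods ×
  2 emission scenarios × 2 labeled climate models, with offsets rising
  across periods and scenarios.

**Realism and limits.** The generator reproduces the features the
pipeline is sensitive to — seasonality, day-to-day autocorrelation,
hockey-stick exposure-response, calendar effects, Poisson counting
noise, suppression — but not multi-region structure, long-term trends,
humidity-driven risk, or lagged (harvesting) effects; lag structure is
exercised separately by acute-effect simulations in the DLNM tests.

## 9. Validation strategy

Every module is tested against independent oracles (textbook formulas,
brute-force recomputation, scipy cross-checks) rather than against its
own output. The acceptance suite (`tests/test_acceptance.py`) fixes
seeds and tolerances up front and checks: exact imputation; the GLM
limit to 1e-6; recovery of the true log-rate curve (RMSE < 0.05 over
the central 90% of exposure support, improving when n quadruples);
recovery of the closed-form attributable percent over 50 seeds (±3
points; null case ±1 point); DLNM reference identity, null-lag interval
coverage ≥ 90% and acute-direction checks; test-statistic oracles to
1e-10; thermal-index identities; and monotonicity of attribution and
projection in the warming offsets.
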