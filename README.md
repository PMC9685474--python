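# heatattr

Attribution of heat-related illness (HRI) to anthropogenic warming, at
desk scale.

`heatattr` implements the full statistical pipeline used in
climate-health attribution studies of emergency-department HRI visits:

1. **Data handling** — daily region-level series of HRI counts and
   weather, with the surveillance suppression convention (counts below
   five withheld, imputed with the constant 3) built into the I/O layer.
2. **Thermal indices** — apparent temperature, the NWS heat index,
   Steadman's index, humidex, Thom's discomfort index and the Excess
   Heat Factor, plus Spearman screening (ρ > 0.55) of candidate indices
   against the HRI rate.
3. **Exposure-response model** — a generalized additive model: a
   penalized natural cubic regression spline in daily maximum
   temperature (up to five knots) plus categorical calendar covariates,
   fit by penalized IRLS with gamma or Poisson family and log link; the
   penalty weight is chosen by generalized cross-validation (GCV).
4. **Distributed-lag nonlinear model (DLNM)** — a cross-basis over
   exposure and lags 0–5 fit by Poisson regression, reported as relative
   risks against the 70th-percentile reference temperature.
5. **Counterfactual attribution** — observed daily rates are compared
   with the rates the fitted model predicts under a counterfactual
   ("no anthropogenic warming") temperature series; the daily percent
   differences are summarized (median, IQR, per-year), tested (paired
   *t*; chi-square on hot-day frequency at ≥ 30 °C) and converted to
   excess visits per season.
6. **Scenario projection** — a reduced temperature-only model projects
   rates under period × scenario × climate-model temperature series and
   compares them (percent change of medians, paired *t*, one-way ANOVA).
7. **Synthetic data generator** — a first-class component producing
   factual, counterfactual and scenario series with *closed-form ground
   truth*, so every stage of the pipeline can be validated end to end
   without restricted health data.

## Worked example

The generator draws four summer seasons (May–September) of daily
maximum temperature — seasonal half-sine plus AR(1) noise — and Poisson
HRI counts from a known log-linear-above-knee risk curve. With the
default warming offset of 1.0 °C the true attributable percent is known
in closed form (≈ 15%).

```python
import warnings
from heatattr import (
    GeneratorConfig, generate_dataset, impute_suppressed,
    add_calendar_covariates, compute_rate, build_design, fit_smooth,
    run_attribution,
)

cfg = GeneratorConfig(seed=7)
data = generate_dataset(cfg)
records = add_calendar_covariates(impute_suppressed(data["factual"]))
rates = compute_rate(records["hri_count"], records["population"])

design = build_design(records["tmax"].to_numpy(), n_basis=4,
                      covariates=records[["dow"]])
fit = fit_smooth(rates, design, family="gamma")
print(f"edf={fit.edf:.2f}  lambda={fit.lam:.3g}  "
      f"deviance explained={fit.deviance_explained:.1%}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    att = run_attribution(records, fit, data["counterfactual"])
print(f"true attributable percent: {data['truth']['attributable_percent']:.2f}")
print(f"estimated median (IQR):    {att.median_pct:.2f} "
      f"({att.iqr_pct[0]:.2f}, {att.iqr_pct[1]:.2f})")
print(f"mean rate observed vs counterfactual: "
      f"{att.mean_rate_observed:.3f} vs {att.mean_rate_counterfactual:.3f}")
print(f"hot days (>=30 C): {att.hot_days_factual} vs {att.hot_days_counterfactual}")
print(f"excess visits per season: {att.attributable_visits_per_season}")
```

Output:

```
edf=8.00  lambda=1e+07  deviance explained=64.1%
true attributable percent: 15.02
estimated median (IQR):    14.51 (-5.71, 32.82)
mean rate observed vs counterfactual: 0.443 vs 0.387
hot days (>=30 C): 315 vs 227
excess visits per season: 342.7
```

The estimated median attributable percent (14.51%) recovers the
closed-form truth (15.02%) to within sampling noise. The wide IQR is
expected: the daily attributable percent divides a single Poisson count
by a smooth prediction, so individual days are noisy even when the
pooled median is accurate.

### Command-line interface

The same pipeline is available as subcommands of `heatattr`:

```bash
heatattr simulate --seed 7 --out-dir fixtures
heatattr fit --in fixtures/factual.csv --family gamma --nbasis 4 \
         --covariates dow --out fit.json
heatattr attribute --in fixtures/factual.csv --fit fit.json \
         --counterfactual fixtures/counterfactual.csv --out attribution.json
heatattr dlnm --in fixtures/factual.csv --lagmax 5 --ref-pct 70 --out rr.csv
heatattr project --fit fit.json --scenarios fixtures/scenarios.csv --out proj.json
heatattr metrics --in fixtures/factual.csv --out metrics.csv
```

which prints, for the same seed:

```
wrote fixtures to fixtures (seed=7)
fit: family=gamma edf=8.00 dev_expl=0.641 aic=-993.6
median attributable percent 14.51% (IQR -5.71, 32.82); wrote attribution.json
reference 31.57 °C; wrote rr.csv
```

(`project` requires a fit without calendar covariates; pass
`--covariates none` to `fit` for that model.)

## Layout

```
src/heatattr/
  io.py          CSV contract, suppression/imputation, rates, screening
  metrics.py     thermal indices
  basis.py       natural cubic spline basis + exact curvature penalty
  smooth.py      penalized GAM (gamma/Poisson, log link, GCV)
  dlnm.py        cross-basis, Poisson lag model, RR prediction
  attribution.py counterfactual attribution report
  projection.py  scenario projection and comparisons
  stats.py       paired t, hot-day chi-square, one-way ANOVA
  simulate.py    synthetic generator with closed-form ground truth
  cli.py         `heatattr` command-line interface
```
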