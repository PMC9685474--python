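"""Counterfactual attribution of the HRI burden to anthropogenic warming.

The procedure: predict the daily HRI rate that the fitted exposure-response
model implies for the counterfactual ("natural simulation") temperatures,
keeping the factual calendar covariates, and compare it with the observed
daily rates.  The daily attributable percent is

    100 * (observed - counterfactual) / counterfactual,

summarized as a median and interquartile range per calendar year; the mean
daily rate difference is tested with a paired t-test, the change in hot-day
(tmax >= 30 °C) frequency with a Pearson chi-square, and the rate
difference is converted to expected excess ED visits per summer season.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import compute_rate
from .smooth import SmoothFit, predict_rate
from .stats import PairedT, ChiSquare, paired_t, hot_day_chisq

__all__ = [
    "AttributionSummary",
    "attributable_percent",
    "attributable_visits",
    "run_attribution",
]

HOT_DAY_THRESHOLD = 30.0  # °C


@dataclass
class AttributionSummary:
    """Everything the attribution stage reports."""

    daily_pct: pd.Series                 # indexed by date
    per_year: pd.DataFrame               # year, median, q25, q75
    median_pct: float                    # pooled over all days
    iqr_pct: tuple[float, float]
    mean_rate_observed: float            # per 100,000
    mean_rate_counterfactual: float
    paired_t: PairedT
    hot_day_test: ChiSquare
    hot_days_factual: int
    hot_days_counterfactual: int
    attributable_visits_per_season: float
    n_days: int

    def to_dict(self) -> dict:
        return {
            "median_pct": self.median_pct,
            "iqr_pct": list(self.iqr_pct),
            "per_year": self.per_year.to_dict(orient="records"),
            "mean_rate_observed": self.mean_rate_observed,
            "mean_rate_counterfactual": self.mean_rate_counterfactual,
            "paired_t": {
                "statistic": self.paired_t.statistic,
                "df": self.paired_t.df,
                "pvalue": self.paired_t.pvalue,
                "mean_diff": self.paired_t.mean_diff,
            },
            "hot_day_chisq": {
                "statistic": self.hot_day_test.statistic,
                "df": self.hot_day_test.df,
                "pvalue": self.hot_day_test.pvalue,
                "hot_days_factual": self.hot_days_factual,
                "hot_days_counterfactual": self.hot_days_counterfactual,
            },
            "attributable_visits_per_season": self.attributable_visits_per_season,
            "n_days": self.n_days,
        }


def attributable_percent(observed_rates, counterfactual_rates, years=None):
    """Daily attributable percent plus per-year median/IQR summaries.

    Returns ``(daily_pct, per_year)``; ``per_year`` is empty when ``years``
    is not supplied.  Errors if any counterfactual rate is non-positive
    (the gamma prediction path guarantees positivity).
    """
    obs = np.asarray(observed_rates, dtype=float)
    cf = np.asarray(counterfactual_rates, dtype=float)
    if obs.shape != cf.shape:
        raise ValueError("series must be aligned and of equal length")
    if np.any(cf <= 0):
        raise ValueError("counterfactual rates must be strictly positive")
    pct = 100.0 * (obs - cf) / cf
    if years is None:
        per_year = pd.DataFrame(columns=["year", "median", "q25", "q75"])
    else:
        df = pd.DataFrame({"year": np.asarray(years), "pct": pct})
        per_year = (
            df.groupby("year")["pct"]
            .agg(median="median", q25=lambda s: s.quantile(0.25),
                 q75=lambda s: s.quantile(0.75))
            .reset_index()
        )
    return pct, per_year


def attributable_visits(
    observed_rates, counterfactual_rates, population: float, season_days: int = 152
) -> float:
    """Expected excess ED visits per summer season.

    Mean daily rate difference (per 100,000) times population / 1e5 times
    the number of season days, rounded to one decimal.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    obs = np.asarray(observed_rates, dtype=float)
    cf = np.asarray(counterfactual_rates, dtype=float)
    diff = float(obs.mean() - cf.mean())
    return round(diff * population / 1e5 * season_days, 1)


def run_attribution(
    records: pd.DataFrame,
    fit: SmoothFit,
    counterfactual: pd.DataFrame,
    hot_threshold: float = HOT_DAY_THRESHOLD,
    season_days: int = 152,
) -> AttributionSummary:
    """Full attribution pipeline for one region.

    ``records`` is the imputed factual table with calendar covariates
    (columns ``date``, ``tmax``, ``hri_count``, ``population`` plus the
    covariates the fit was trained with); ``counterfactual`` carries
    ``date`` and ``tmax``.  The two must cover exactly the same dates.
    """
    rec = records.sort_values("date").reset_index(drop=True)
    cf = counterfactual.sort_values("date").reset_index(drop=True)
    d_f = pd.DatetimeIndex(rec["date"])
    d_c = pd.DatetimeIndex(cf["date"])
    if not d_f.equals(d_c):
        missing = sorted(set(d_f.date).symmetric_difference(set(d_c.date)))
        raise ValueError(
            f"factual and counterfactual dates differ on {len(missing)} day(s): "
            f"{[str(m) for m in missing[:10]]}"
        )
    if rec["hri_count"].isna().any():
        raise ValueError("records contain unimputed suppressed counts")

    observed = compute_rate(rec["hri_count"].to_numpy(), rec["population"].to_numpy())
    covs = (
        rec[list(fit.covariate_levels.keys())] if fit.has_covariates else None
    )
    cf_pred = predict_rate(fit, cf["tmax"].to_numpy(), covs)

    years = d_f.year
    pct, per_year = attributable_percent(observed, cf_pred, years)
    t = paired_t(observed, cf_pred)
    chi = hot_day_chisq(rec["tmax"].to_numpy(), cf["tmax"].to_numpy(), hot_threshold)
    visits = attributable_visits(
        observed, cf_pred, float(rec["population"].iloc[0]), season_days
    )
    return AttributionSummary(
        daily_pct=pd.Series(pct, index=d_f, name="attributable_pct"),
        per_year=per_year,
        median_pct=float(np.median(pct)),
        iqr_pct=(float(np.percentile(pct, 25)), float(np.percentile(pct, 75))),
        mean_rate_observed=float(observed.mean()),
        mean_rate_counterfactual=float(cf_pred.mean()),
        paired_t=t,
        hot_day_test=chi,
        hot_days_factual=int(chi.table[0, 0]),
        hot_days_counterfactual=int(chi.table[1, 0]),
        attributable_visits_per_season=visits,
        n_days=len(rec),
    )
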