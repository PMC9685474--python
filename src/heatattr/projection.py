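"""Project HRI rates under emission scenarios with a reduced (spline-only)
exposure-response model.

The reduced model carries no calendar covariates — scenario series span
future calendars — so projected rates depend on daily maximum temperature
alone.  Summaries per (period, scenario, model) cell: pooled-summer-day
median and IQR of the projected rate, the percent change of medians between
the high and intermediate scenario within each period, a paired t-test
between scenarios (paired by position in the pooled day sequence), and a
one-way ANOVA across the three periods within each scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smooth import SmoothFit, predict_rate
from .stats import Anova, PairedT, one_way_anova, paired_t

__all__ = [
    "project_rates",
    "percent_change_median",
    "scenario_tests",
    "summarize_projection",
    "ProjectionSummary",
]


def project_rates(fit: SmoothFit, tmax) -> np.ndarray:
    """Daily projected rates from a covariate-free (reduced) fit.

    Future temperatures may exceed the training range; the spline's linear
    extension is used there and a warning reports how many days it covers.
    """
    if fit.has_covariates:
        raise ValueError(
            "projection requires a reduced fit without calendar covariates"
        )
    return predict_rate(fit, np.asarray(tmax, dtype=float))


def percent_change_median(rates_a, rates_b) -> float:
    """Percent change of the median rate, b relative to a."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty rate series")
    ma = float(np.median(a))
    if ma == 0:
        raise ValueError("reference median is zero")
    return 100.0 * (float(np.median(b)) - ma) / ma


def scenario_tests(rates_by_scenario: dict[str, np.ndarray],
                   rates_by_period: dict[str, np.ndarray]):
    """Paired t between two scenarios and ANOVA across periods.

    ``rates_by_scenario`` maps exactly two scenario labels to aligned daily
    rate series (within one period); ``rates_by_period`` maps period labels
    to series (within one scenario).
    """
    if len(rates_by_scenario) != 2:
        raise ValueError("paired scenario test needs exactly two scenarios")
    (la, a), (lb, b) = sorted(rates_by_scenario.items())
    if len(a) != len(b):
        raise ValueError("scenario series are not aligned")
    t = paired_t(b, a)  # high minus intermediate when labels sort that way
    anova = one_way_anova(*[rates_by_period[p] for p in sorted(rates_by_period)])
    return t, anova


@dataclass
class ProjectionSummary:
    """Scenario projection report."""

    cells: pd.DataFrame              # period, scenario, model, median, q25, q75, n
    pct_change: pd.DataFrame         # period, model, pct_change (high vs intermediate)
    paired_t: dict                   # (period, model) -> PairedT
    anova: dict                      # (scenario, model) -> Anova

    def to_dict(self) -> dict:
        return {
            "cells": self.cells.to_dict(orient="records"),
            "pct_change_high_vs_intermediate": self.pct_change.to_dict(orient="records"),
            "paired_t": {
                f"{p}|{m}": {"statistic": t.statistic, "df": t.df, "pvalue": t.pvalue}
                for (p, m), t in self.paired_t.items()
            },
            "anova": {
                f"{s}|{m}": {
                    "F": a.statistic,
                    "df_between": a.df_between,
                    "df_within": a.df_within,
                    "pvalue": a.pvalue,
                }
                for (s, m), a in self.anova.items()
            },
        }


def summarize_projection(fit: SmoothFit, scenarios: pd.DataFrame) -> ProjectionSummary:
    """Run the full projection stage on a tagged scenario table.

    ``scenarios`` has columns ``period``, ``scenario``, ``model``, ``tmax``
    (one row per scenario-day).  Deterministic: identical inputs yield an
    identical summary.
    """
    need = {"period", "scenario", "model", "tmax"}
    if not need.issubset(scenarios.columns):
        raise ValueError(f"scenario table needs columns {sorted(need)}")

    df = scenarios.copy()
    df["rate"] = project_rates(fit, df["tmax"].to_numpy())

    cells = (
        df.groupby(["period", "scenario", "model"], sort=True)["rate"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n="size",
        )
        .reset_index()
    )

    pct_rows, t_by, anova_by = [], {}, {}
    for (period, model), grp in df.groupby(["period", "model"], sort=True):
        by_scen = {
            s: g["rate"].to_numpy() for s, g in grp.groupby("scenario", sort=True)
        }
        if set(by_scen) == {"intermediate", "high"}:
            pct_rows.append(
                {
                    "period": period,
                    "model": model,
                    "pct_change": percent_change_median(
                        by_scen["intermediate"], by_scen["high"]
                    ),
                }
            )
            t_by[(period, model)] = paired_t(by_scen["high"], by_scen["intermediate"])
    for (scenario, model), grp in df.groupby(["scenario", "model"], sort=True):
        by_period = {
            p: g["rate"].to_numpy() for p, g in grp.groupby("period", sort=True)
        }
        if len(by_period) >= 2:
            anova_by[(scenario, model)] = one_way_anova(*by_period.values())

    return ProjectionSummary(
        cells=cells,
        pct_change=pd.DataFrame(pct_rows),
        paired_t=t_by,
        anova=anova_by,
    )
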