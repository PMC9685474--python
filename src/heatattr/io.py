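"""Reading daily HRI/weather series, suppression handling, rates, calendar.

The on-disk contract is one CSV row per region-day with columns ``date``
(ISO-8601), ``region``, ``tmax_c``, ``tmin_c``, ``tmean_c``, ``tdew_c``,
``hri_count`` and ``population``.  A withheld (suppressed) daily count —
days with fewer than five visits are suppressed for confidentiality — is
encoded as an empty field or the sentinel ``"S"``; both are accepted.

In memory a daily series is a :class:`pandas.DataFrame` with columns
``date``, ``region``, ``tmax``, ``tmin``, ``tmean``, ``tdew``,
``hri_count`` (NaN while suppressed and not yet imputed), ``suppressed``
(bool) and ``population``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COLUMNS",
    "read_daily_series",
    "write_daily_series",
    "impute_suppressed",
    "compute_rate",
    "add_calendar_covariates",
    "screen_predictors",
    "SUPPRESSION_THRESHOLD",
    "IMPUTED_VALUE",
]

COLUMNS = [
    "date",
    "region",
    "tmax_c",
    "tmin_c",
    "tmean_c",
    "tdew_c",
    "hri_count",
    "population",
]

#: counts below this are withheld in the raw data
SUPPRESSION_THRESHOLD = 5
#: constant substituted for a withheld count
IMPUTED_VALUE = 3

_SENTINELS = {"", "S", "s", "NA"}


def read_daily_series(path, region: str | None = None) -> pd.DataFrame:
    """Read a daily series CSV, optionally restricted to one region.

    Returns one row per region-day sorted by (region, date) with the
    ``suppressed`` flag set where the count field carries a sentinel.
    Raises on missing columns, unparseable dates (with the line number) and
    duplicated region-dates.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    if region is not None:
        raw = raw[raw["region"] == region].reset_index(drop=True)
    if raw.empty:
        return pd.DataFrame(
            columns=[
                "date", "region", "tmax", "tmin", "tmean", "tdew",
                "hri_count", "suppressed", "population",
            ]
        )

    dates = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        # +2: header line plus 1-based indexing
        line = int(np.nonzero(dates.isna().to_numpy())[0][0]) + 2
        raise ValueError(f"{path.name}: unparseable date on line {line}")

    counts_raw = raw["hri_count"].str.strip()
    suppressed = counts_raw.isin(_SENTINELS)
    counts = pd.to_numeric(counts_raw.where(~suppressed, other=np.nan))

    out = pd.DataFrame(
        {
            "date": dates,
            "region": raw["region"],
            "tmax": pd.to_numeric(raw["tmax_c"]),
            "tmin": pd.to_numeric(raw["tmin_c"]),
            "tmean": pd.to_numeric(raw["tmean_c"]),
            "tdew": pd.to_numeric(raw["tdew_c"]),
            "hri_count": counts,
            "suppressed": suppressed.to_numpy(),
            "population": pd.to_numeric(raw["population"]).astype(int),
        }
    )
    dup = out.duplicated(subset=["region", "date"])
    if dup.any():
        d = out.loc[dup, ["region", "date"]].iloc[0]
        raise ValueError(
            f"{path.name}: duplicate region-date ({d['region']}, {d['date'].date()})"
        )
    if (out["population"] <= 0).any():
        raise ValueError(f"{path.name}: population must be positive")
    return out.sort_values(["region", "date"], kind="stable").reset_index(drop=True)


def write_daily_series(df: pd.DataFrame, path) -> None:
    """Write a daily series back to the CSV contract (sentinel ``S``)."""
    out = pd.DataFrame(
        {
            "date": pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d"),
            "region": df["region"],
            "tmax_c": df["tmax"],
            "tmin_c": df["tmin"],
            "tmean_c": df["tmean"],
            "tdew_c": df["tdew"],
            "hri_count": [
                "S" if s else str(int(c))
                for s, c in zip(df["suppressed"], df["hri_count"].fillna(0))
            ],
            "population": df["population"],
        }
    )
    out.to_csv(path, index=False)


def impute_suppressed(df: pd.DataFrame, value: int = IMPUTED_VALUE) -> pd.DataFrame:
    """Replace withheld counts with a fixed constant (default 3).

    The constant is the value published for the suppressed range;
    non-suppressed counts pass through unchanged.  Idempotent.
    """
    out = df.copy()
    out.loc[out["suppressed"], "hri_count"] = float(value)
    out["hri_count"] = out["hri_count"].astype(float)
    return out


def compute_rate(count, population):
    """Daily rate per 100,000 persons: ``count / population * 1e5``."""
    count = np.asarray(count, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("population must be positive")
    if np.any(count < 0):
        raise ValueError("count must be non-negative")
    return count / population * 1e5


_WEEKEND = {"Sat", "Sun"}
_DOW = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


def add_calendar_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``dow`` (7-level), ``wday`` (weekend/weekday), ``month``, ``year``."""
    out = df.copy()
    dates = pd.to_datetime(out["date"])
    out["dow"] = dates.dt.dayofweek.map(dict(enumerate(_DOW)))
    out["wday"] = out["dow"].map(lambda d: "weekend" if d in _WEEKEND else "weekday")
    out["month"] = dates.dt.strftime("%b")
    out["year"] = dates.dt.year.astype(str)
    return out


def screen_predictors(
    metric_series: dict[str, np.ndarray],
    rate_series: np.ndarray,
    threshold: float = 0.55,
):
    """Spearman screening of candidate heat metrics against the HRI rate.

    Returns ``(rho, retained)`` where ``rho`` maps each metric name to its
    Spearman rank correlation (NaN for a constant series, which is never
    retained) and ``retained`` lists metrics with ``rho > threshold``.
    """
    rate = np.asarray(rate_series, dtype=float)
    if rate.size < 3:
        raise ValueError("need at least 3 observations")
    rho: dict[str, float] = {}
    retained: list[str] = []
    for name, series in metric_series.items():
        s = np.asarray(series, dtype=float)
        if s.size != rate.size:
            raise ValueError(f"metric {name!r} length mismatch")
        if np.all(s == s[0]) or np.all(rate == rate[0]):
            rho[name] = float("nan")
            continue
        r = stats.spearmanr(s, rate).statistic
        rho[name] = float(r)
        if r > threshold:
            retained.append(name)
    return rho, retained
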