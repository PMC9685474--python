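"""Thermal indices used to screen heat metrics against HRI rates.

All public functions take and return degrees Celsius (the humidex is a
unitless index on a Celsius-like scale); internal arithmetic runs in the
native units of each published formula (Fahrenheit for the NWS heat index,
hPa for vapor pressures) with conversion at the boundary.  Every index is a
pure per-day map except the Excess Heat Factor, which needs a 3-day and a
30-day window.

Formulas:

* saturation vapor pressure — Magnus form, ``e_s(T) = 6.112 exp(17.67 T /
  (T + 243.5))`` hPa;
* relative humidity — ``100 e_s(Td) / e_s(T)``, clamped to [0, 100];
* apparent temperature — Steadman's non-wind form ``AT = T + 0.33 e - 4.00``
  with ``e`` the vapor pressure from the dew point (wind term omitted: the
  daily data model carries no wind speed);
* NWS heat index — the operational National Weather Service algorithm:
  simple Steadman average first, Rothfusz regression with the low- and
  high-humidity adjustments when the average reaches 80 °F;
* humidex — Environment Canada dew-point form;
* thermal discomfort index — Thom's form.
* Excess Heat Factor — Nairn–Fawcett: 3-day mean excess over a
  climatological 95th percentile times an acclimatization factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "saturation_vapor_pressure",
    "relative_humidity",
    "apparent_temperature",
    "nws_heat_index",
    "steadman_heat_index",
    "humidex",
    "discomfort_index",
    "excess_heat_factor",
    "metric_table",
]


def _c_to_f(t):
    return t * 9.0 / 5.0 + 32.0


def _f_to_c(t):
    return (t - 32.0) * 5.0 / 9.0


def saturation_vapor_pressure(t):
    """Magnus saturation vapor pressure over water, hPa (t in °C)."""
    t = np.asarray(t, dtype=float)
    return 6.112 * np.exp(17.67 * t / (t + 243.5))


def relative_humidity(t, td):
    """Relative humidity (%) from air and dew-point temperature (°C).

    Dew point above air temperature is clamped to saturation (100%).
    """
    t = np.asarray(t, dtype=float)
    td = np.asarray(td, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(td))):
        raise ValueError("non-finite temperature or dew point")
    rh = 100.0 * saturation_vapor_pressure(td) / saturation_vapor_pressure(t)
    return np.clip(rh, 0.0, 100.0)


def apparent_temperature(t, td):
    """Steadman apparent temperature (°C), non-wind form.

    ``AT = T + 0.33 e - 4.00`` with ``e`` (hPa) the Magnus vapor pressure at
    the dew point.  Applied to daily maximum temperature this is the daily
    maximum apparent temperature (MAT).
    """
    t = np.asarray(t, dtype=float)
    e = saturation_vapor_pressure(td)
    return t + 0.33 * e - 4.00


def steadman_heat_index(t, rh):
    """Steadman's simple heat index (°C) from T (°C) and RH (%).

    ``HI_F = 0.5 (T_F + 61.0 + 1.2 (T_F - 68.0) + 0.094 RH)`` — the same
    expression the NWS algorithm uses below its hot-regime threshold.
    """
    tf = _c_to_f(np.asarray(t, dtype=float))
    rh = np.asarray(rh, dtype=float)
    hi_f = 0.5 * (tf + 61.0 + (tf - 68.0) * 1.2 + rh * 0.094)
    return _f_to_c(hi_f)


def nws_heat_index(t, rh):
    """Operational NWS heat index (°C) from T (°C) and RH (%).

    The simple Steadman value is averaged with the temperature; when that
    average reaches 80 °F the Rothfusz regression replaces it, with the
    published low-RH (RH < 13%, 80–112 °F) and high-RH (RH > 85%, 80–87 °F)
    adjustments.
    """
    tf = np.atleast_1d(_c_to_f(np.asarray(t, dtype=float)))
    rh = np.atleast_1d(np.asarray(rh, dtype=float)).astype(float)
    if rh.size == 1 and tf.size > 1:
        rh = np.full_like(tf, rh[0])
    simple = 0.5 * (tf + 61.0 + (tf - 68.0) * 1.2 + rh * 0.094)
    hi = (simple + tf) / 2.0

    hot = hi >= 80.0
    if np.any(hot):
        T, R = tf[hot], rh[hot]
        roth = (
            -42.379
            + 2.04901523 * T
            + 10.14333127 * R
            - 0.22475541 * T * R
            - 6.83783e-3 * T**2
            - 5.481717e-2 * R**2
            + 1.22874e-3 * T**2 * R
            + 8.5282e-4 * T * R**2
            - 1.99e-6 * T**2 * R**2
        )
        low = (R < 13.0) & (T >= 80.0) & (T <= 112.0)
        roth = np.where(
            low,
            roth - ((13.0 - R) / 4.0) * np.sqrt(np.clip(17.0 - np.abs(T - 95.0), 0, None) / 17.0),
            roth,
        )
        high = (R > 85.0) & (T >= 80.0) & (T <= 87.0)
        roth = np.where(high, roth + ((R - 85.0) / 10.0) * ((87.0 - T) / 5.0), roth)
        hi[hot] = roth
    out = _f_to_c(hi)
    return out if out.size > 1 else float(out[0])


def humidex(t, td):
    """Humidex from T (°C) and dew point (°C), Environment Canada form.

    ``H = T + 0.5555 (e - 10)`` with
    ``e = 6.11 exp(5417.7530 (1/273.16 - 1/(273.15 + Td)))`` hPa.
    """
    t = np.asarray(t, dtype=float)
    td = np.asarray(td, dtype=float)
    e = 6.11 * np.exp(5417.7530 * (1.0 / 273.16 - 1.0 / (273.15 + td)))
    return t + 0.5555 * (e - 10.0)


def discomfort_index(t, rh):
    """Thom's thermal discomfort index (°C): ``T - 0.55 (1 - 0.01 RH)(T - 14.5)``."""
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    return t - 0.55 * (1.0 - 0.01 * rh) * (t - 14.5)


def excess_heat_factor(tmean, climatology_p95: float | None = None):
    """Excess Heat Factor series from daily mean temperature (°C).

    ``EHI_sig(i)``  = 3-day mean ``T_{i-2..i}`` minus the climatological 95th
    percentile; ``EHI_accl(i)`` = 3-day mean minus the preceding 30-day mean
    ``T_{i-32..i-3}``; ``EHF(i) = EHI_sig(i) * max(1, EHI_accl(i))``.  The
    first 32 positions, which lack a full history, are NaN.  When
    ``climatology_p95`` is not supplied it is taken as the 95th percentile
    of the input series itself.
    """
    tmean = np.asarray(tmean, dtype=float)
    n = tmean.size
    if n <= 32:
        raise ValueError("EHF needs more than 32 days of history")
    if climatology_p95 is None:
        climatology_p95 = float(np.percentile(tmean, 95))
    s = pd.Series(tmean)
    m3 = s.rolling(3).mean().to_numpy()
    m30 = s.rolling(30).mean().shift(3).to_numpy()
    sig = m3 - climatology_p95
    accl = m3 - m30
    ehf = sig * np.maximum(1.0, accl)
    ehf[:32] = np.nan
    return ehf


def metric_table(
    df: pd.DataFrame,
    tdi_on: str = "tmax",
    ehf_on: str = "tmean",
    climatology_p95: float | None = None,
) -> pd.DataFrame:
    """Append the full index suite to a daily table.

    Expects columns ``tmax``, ``tmean``, ``tdew``; adds ``rh``, ``mat``,
    ``nws_hi``, ``steadman_hi``, ``humidex``, ``tdi``, ``ehf``.  The EHF is
    computed per contiguous series as given (the caller is responsible for
    passing one region at a time).
    """
    out = df.copy()
    rh = relative_humidity(out["tmax"].to_numpy(), out["tdew"].to_numpy())
    out["rh"] = rh
    out["mat"] = apparent_temperature(out["tmax"].to_numpy(), out["tdew"].to_numpy())
    out["nws_hi"] = nws_heat_index(out["tmax"].to_numpy(), rh)
    out["steadman_hi"] = steadman_heat_index(out["tmax"].to_numpy(), rh)
    out["humidex"] = humidex(out["tmax"].to_numpy(), out["tdew"].to_numpy())
    out["tdi"] = discomfort_index(out[tdi_on].to_numpy(), rh)
    out["ehf"] = excess_heat_factor(out[ehf_on].to_numpy(), climatology_p95)
    return out
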