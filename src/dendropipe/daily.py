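"""Daily summaries of half-hourly weather, including vapor pressure deficit.

Saturation vapor pressure follows the Magnus-type form

    SVP = 6.11 * exp(17.2693882 * AT / (AT + 237.3))        [hPa, AT in C]

and ambient vapor pressure is obtained from relative humidity RH (%) and
barometric pressure P (hPa) as

    VP = RH * SVP * P / (RH * SVP + 100 * (P - SVP))        [hPa]

Vapor pressure deficit (SVP - VP) is computed per half hour and summarized
by the daily mean -- deliberately not from daily-mean inputs, because the
formulas are nonlinear.  At RH = 100 the VP expression collapses to SVP
exactly, so VPD is zero; at RH = 0 it is zero.

A calendar day (local midnight to midnight) is summarized only when at least
``coverage_threshold`` of its 48 slots are present; totals, extremes and
means run over present slots only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import SLOTS_PER_DAY

__all__ = [
    "DomainError",
    "svp",
    "vp",
    "vpd_halfhourly",
    "summarize_day",
    "summarize_daily",
    "monthly_climatology",
    "DAILY_COLUMNS",
]

DAILY_COLUMNS = [
    "prec_total", "tair_max", "tair_min", "tair_mean",
    "tsoil_max", "tsoil_min", "tsoil_mean", "soil_moisture_mean",
    "rh_mean", "pressure_mean", "solrad_total",
    "wind_speed_mean", "wind_gust_max", "vpd_mean",
]


class DomainError(ValueError):
    """Input outside the mathematical domain of the vapor pressure formulas."""


def svp(at):
    """Saturation vapor pressure (hPa) at air temperature ``at`` (C).

    Strictly increasing and positive; equals 6.11 hPa at 0 C.  NaN inputs
    propagate; finite inputs at or below -237.3 C are a domain error.
    """
    a = np.asarray(at, dtype=float)
    if np.any(a[np.isfinite(a)] <= -237.3):
        raise DomainError("svp undefined at or below -237.3 C")
    out = 6.11 * np.exp(17.2693882 * a / (a + 237.3))
    return float(out) if np.isscalar(at) else out


def vp(svp_val, rh, p):
    """Ambient vapor pressure (hPa) from SVP (hPa), RH (%) and pressure (hPa).

    Requires rh in [0, 100] and p > svp_val > 0 (otherwise the denominator
    degenerates).  Bounded by 0 <= vp <= svp_val, with equality at RH = 0
    and RH = 100 respectively.
    """
    s = np.asarray(svp_val, dtype=float)
    r = np.asarray(rh, dtype=float)
    pr = np.asarray(p, dtype=float)
    finite = np.isfinite(r)
    if np.any((r[finite] < 0) | (r[finite] > 100)):
        raise DomainError("rh must lie in [0, 100]")
    both = np.isfinite(s) & np.isfinite(pr)
    if np.any(s[both] <= 0) or np.any(pr[both] <= s[both]):
        raise DomainError("vp requires p > svp > 0")
    out = r * s * pr / (r * s + 100.0 * (pr - s))
    scalar = np.isscalar(svp_val) and np.isscalar(rh) and np.isscalar(p)
    return float(out) if scalar else out


def vpd_halfhourly(tair, rh, pressure):
    """Half-hourly vapor pressure deficit SVP(tair) - VP (hPa), >= 0.

    Missing (NaN) in any input yields missing VPD, which is then excluded
    from the daily mean.
    """
    s = svp(tair)
    v = vp(s, rh, pressure)
    out = np.maximum(np.asarray(s) - np.asarray(v), 0.0)
    mask = np.isnan(np.asarray(tair, dtype=float)) | \
        np.isnan(np.asarray(rh, dtype=float)) | \
        np.isnan(np.asarray(pressure, dtype=float))
    out = np.where(mask, np.nan, out)
    scalar = np.isscalar(tair) and np.isscalar(rh) and np.isscalar(pressure)
    return float(out) if scalar else out


def _summaries(group: pd.DataFrame) -> dict:
    vpd = vpd_halfhourly(group["tair"].to_numpy(),
                         group["rh"].to_numpy(),
                         group["pressure"].to_numpy())
    def total(col):
        v = group[col].dropna()
        return v.sum() if len(v) else np.nan
    return {
        "prec_total": total("precip"),
        "tair_max": group["tair"].max(),
        "tair_min": group["tair"].min(),
        "tair_mean": group["tair"].mean(),
        "tsoil_max": group["tsoil"].max(),
        "tsoil_min": group["tsoil"].min(),
        "tsoil_mean": group["tsoil"].mean(),
        "soil_moisture_mean": group["soil_moisture"].mean(),
        "rh_mean": group["rh"].mean(),
        "pressure_mean": group["pressure"].mean(),
        "solrad_total": total("solrad"),
        "wind_speed_mean": group["wind_speed"].mean(),
        "wind_gust_max": group["wind_gust"].max(),
        "vpd_mean": float(np.nanmean(vpd)) if np.any(~np.isnan(vpd)) else np.nan,
    }


def summarize_daily(
    weather: pd.DataFrame, coverage_threshold: float = 0.75
) -> pd.DataFrame:
    """Collapse a half-hourly weather frame to one row per calendar day.

    ``coverage`` is the fraction of the 48 slots with at least one present
    channel; a day below the threshold keeps its coverage value but all its
    summaries are set missing.  An entirely empty day is missing, not zeros.
    """
    if weather.empty:
        raise ValueError("no weather records to summarize")
    day = weather.index.floor("D")
    rows = {}
    for d, group in weather.groupby(day):
        present = group.notna().any(axis=1).sum()
        rec = _summaries(group)
        rec["coverage"] = present / SLOTS_PER_DAY
        rows[d] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "date"
    out = out.reindex(columns=[*DAILY_COLUMNS, "coverage"])
    low = out["coverage"] < coverage_threshold
    out.loc[low, DAILY_COLUMNS] = np.nan
    return out


def summarize_day(records: pd.DataFrame, coverage_threshold: float = 0.75) -> pd.Series:
    """Summarize records belonging to a single calendar day."""
    days = records.index.floor("D").unique()
    if len(days) != 1:
        raise ValueError("summarize_day expects records from one calendar day")
    return summarize_daily(records, coverage_threshold).iloc[0]


def monthly_climatology(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-month climatology across years.

    Totals (precipitation, solar radiation) become mean monthly *totals*
    (the monthly sum within each year, averaged across years); everything
    else is the mean of the daily values.  A month with zero retained days
    is missing.
    """
    d = daily.dropna(how="all", subset=DAILY_COLUMNS)
    if d.empty:
        raise ValueError("no retained days for climatology")
    idx = pd.DatetimeIndex(d.index)
    month = idx.month
    ym = pd.PeriodIndex(idx, freq="M")

    out = pd.DataFrame(index=pd.RangeIndex(1, 13, name="month"))
    for col in ("prec_total", "solrad_total"):
        sums = d[col].groupby(ym).sum(min_count=1)
        out[col] = sums.groupby(sums.index.month).mean()
    mean_cols = [c for c in DAILY_COLUMNS if c not in ("prec_total", "solrad_total")]
    for col in mean_cols:
        out[col] = d[col].groupby(month).mean()
    out["n_days"] = pd.Series(d[DAILY_COLUMNS].notna().any(axis=1).groupby(month).sum(),
                              dtype=float)
    return out
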