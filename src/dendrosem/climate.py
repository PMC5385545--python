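"""Hargreaves potential evapotranspiration and the climatic water balance.

The moisture variable used throughout the pipeline is the monthly climatic
water balance W = P - PET, where PET is estimated from the diurnal
temperature range with the Hargreaves (1985) equation and extraterrestrial
radiation computed with the FAO-56 formulation at the mid-month day of year.
Summer (June-August) means of W, standardized to z-scores, are the drought
index the tree-ring series are regressed against.
"""

from __future__ import annotations

import calendar
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "extraterrestrial_radiation",
    "hargreaves_pet",
    "water_balance",
    "seasonal_mean",
    "water_year_total",
    "zscore",
]

# FAO-56 constants
_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
_MJ_TO_MM = 0.408  # latent-heat conversion, mm per MJ m-2

# day-of-year of the 15th of each month (365-day calendar)
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])

# Hargreaves 1985 coefficients (classical form)
HARGREAVES_COEF = 0.0023
HARGREAVES_TEMP_OFFSET = 17.8


def extraterrestrial_radiation(latitude_deg: float, month) -> np.ndarray | float:
    """Extraterrestrial radiation Ra in mm/day water equivalent.

    FAO-56 daily Ra evaluated at the mid-month day of year (the 15th).
    The sunset-hour-angle argument is clamped to [-1, 1] so polar night
    yields Ra = 0 and polar day the 24-hour maximum.

    Parameters
    ----------
    latitude_deg : float
        Site latitude in decimal degrees, in [-90, 90].
    month : int or array of int
        Calendar month, 1-12.
    """
    if not -90.0 <= latitude_deg <= 90.0:
        raise ValueError(f"latitude {latitude_deg} outside [-90, 90]")
    month = np.asarray(month)
    if np.any((month < 1) | (month > 12)):
        raise ValueError("month must be in 1..12")
    j = _MID_MONTH_DOY[month - 1]
    phi = np.deg2rad(latitude_deg)
    decl = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra_mj = (
        (24.0 * 60.0 / np.pi)
        * _SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
    )
    ra = np.maximum(ra_mj, 0.0) * _MJ_TO_MM
    return float(ra) if ra.ndim == 0 else ra


def _days_in_month(year, month) -> np.ndarray:
    year = np.asarray(year)
    month = np.asarray(month)
    days = np.array(
        [calendar.monthrange(int(y), int(m))[1] for y, m in zip(np.ravel(year), np.ravel(month))]
    )
    return days.reshape(np.broadcast(year, month).shape)


def hargreaves_pet(tmin, tmax, latitude_deg: float, year, month):
    """Monthly Hargreaves reference evapotranspiration in mm/month.

    PET_day = 0.0023 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin), floored at
    zero, then scaled by the (leap-aware) number of days in the month.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin encountered")
    tmean = 0.5 * (tmax + tmin)
    ra = extraterrestrial_radiation(latitude_deg, month)
    pet_day = HARGREAVES_COEF * ra * (tmean + HARGREAVES_TEMP_OFFSET) * np.sqrt(tmax - tmin)
    pet_day = np.maximum(pet_day, 0.0)
    out = pet_day * _days_in_month(year, month)
    return float(out) if np.ndim(out) == 0 else out


def water_balance(climate: pd.DataFrame, latitude_deg: float) -> pd.DataFrame:
    """Attach PET and water balance columns to a long-format monthly table.

    Requires columns year, month, tmin, tmax, prcp. Returns a copy with
    `pet` (mm/month) and `wbal = prcp - pet` (mm/month) added.
    """
    required = ["year", "month", "tmin", "tmax", "prcp"]
    missing_cols = [c for c in required if c not in climate.columns]
    if missing_cols:
        raise ValueError(f"climate table missing columns: {missing_cols}")
    bad = climate[required].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"missing tmin/tmax/prcp in rows: {list(climate.index[bad])[:10]}")
    out = climate.copy()
    out["pet"] = hargreaves_pet(
        out["tmin"].to_numpy(),
        out["tmax"].to_numpy(),
        latitude_deg,
        out["year"].to_numpy(),
        out["month"].to_numpy(),
    )
    out["wbal"] = out["prcp"] - out["pet"]
    return out


def seasonal_mean(
    climate: pd.DataFrame,
    variable: str,
    months: Iterable[int] = (6, 7, 8),
    statistic: str = "mean",
) -> pd.Series:
    """Per-year seasonal mean (or sum) of one monthly variable.

    Years missing any contributing month are dropped with a warning. The
    default June-August window is the season the growth and isotope series
    respond to most strongly at the study latitude.
    """
    months = sorted(set(int(m) for m in months))
    if not months:
        raise ValueError("empty month set")
    if any(m < 1 or m > 12 for m in months):
        raise ValueError(f"invalid months: {months}")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    sub = climate[climate["month"].isin(months)]
    counts = sub.groupby("year")["month"].nunique()
    complete = counts.index[counts == len(months)]
    dropped = counts.index[counts < len(months)]
    if len(dropped):
        warnings.warn(f"dropping years with incomplete season: {list(dropped)}")
    sub = sub[sub["year"].isin(complete)]
    agg = sub.groupby("year")[variable].agg(statistic)
    agg.name = variable
    return agg.sort_index()


def water_year_total(deposition: pd.DataFrame, value_col: str | None = None) -> pd.Series:
    """Water-year totals (previous October through current September).

    Accepts a monthly table (year, month, value) and sums each Oct-Sep
    window, labeling the total by the calendar year of its September.
    An annual table (year, value) is taken as already water-year totals
    and passed through unchanged.
    """
    if value_col is None:
        value_col = [c for c in deposition.columns if c not in ("year", "month")][0]
    if "month" not in deposition.columns:
        out = deposition.set_index("year")[value_col].sort_index()
        out.name = value_col
        return out
    d = deposition.copy()
    # shift Oct-Dec forward into the next water year
    d["wyear"] = d["year"] + (d["month"] >= 10).astype(int)
    counts = d.groupby("wyear")["month"].nunique()
    complete = counts.index[counts == 12]
    dropped = counts.index[counts < 12]
    if len(dropped):
        warnings.warn(f"dropping incomplete water years: {list(dropped)}")
    d = d[d["wyear"].isin(complete)]
    out = d.groupby("wyear")[value_col].sum()
    out.index.name = "year"
    out.name = value_col
    return out.sort_index()


def zscore(series: pd.Series, reference_period: tuple[int, int] | None = None) -> pd.Series:
    """Standardize a year-indexed series to zero mean and unit SD.

    Moments are taken over `reference_period` (inclusive year interval)
    when given, otherwise over the whole series; the transform is then
    applied to every year. Sample SD (ddof=1).
    """
    x = series.dropna()
    if reference_period is not None:
        lo, hi = reference_period
        ref = x[(x.index >= lo) & (x.index <= hi)]
        if len(ref) < 2:
            raise ValueError("reference period covers fewer than 2 years")
    else:
        ref = x
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("zero variance over reference period")
    return (series - ref.mean()) / sd
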