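"""Meteorological and spatial predictors for phenophase models.

Implements the 42 agro-meteorological predictors (monthly/seasonal mean
temperatures and precipitation totals for the current and previous year,
cumulative growing degree days for bases 0..8 degC and cumulative growing
precipitation days) and the 4 spatial predictors (projected coordinates,
altitude, coast distance), all computed strictly from data dated on or
before a phenophase-specific cutoff so that no "future" information leaks
into a predictive model.

The cutoff convention: a phenophase observed typically in month M may only
use data through the last day of M (derived from the training-set mean
onset day-of-year, never from test years).
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CutoffRule",
    "GDD_BASES",
    "meteo_feature_names",
    "spatial_feature_names",
    "cum_gdd",
    "cum_gpd",
    "monthly_and_seasonal_aggregates",
    "cutoff_for",
    "assemble_meteo_features",
    "assemble_spatial_features",
]

GDD_BASES = tuple(range(0, 9))  # 0..8 degC in 1-degree steps
DEFAULT_WET_THRESHOLD_MM = 1.0  # WMO wet-day convention

_MONTHS = [calendar.month_abbr[m].lower() for m in range(1, 13)]


def meteo_feature_names() -> list[str]:
    """The 42 meteorological predictor names, in stable order."""
    names = [f"met_tmean_{m}" for m in _MONTHS]
    names += ["met_tmean_dec_prev"]
    names += [f"met_tmean_prev_{s}" for s in ("djf", "mam", "jja", "son")]
    names += ["met_tmean_winter", "met_tmean_spring"]
    names += [f"met_prec_{m}" for m in _MONTHS]
    names += ["met_prec_dec_prev"]
    names += [f"met_gdd_b{b}" for b in GDD_BASES]
    names += ["met_gpd"]
    assert len(names) == 42
    return names


def spatial_feature_names() -> list[str]:
    return ["sp_x_km", "sp_y_km", "sp_altitude_m", "sp_coast_km"]


@dataclass(frozen=True)
class CutoffRule:
    """Last usable calendar month for one phenophase's predictors."""

    phenophase_id: str
    month: int  # 1..12

    def cutoff_date(self, year: int) -> pd.Timestamp:
        last = calendar.monthrange(year, self.month)[1]
        return pd.Timestamp(year, self.month, last)


def cutoff_for(phenophase_id: str, mean_onset_doy: float) -> CutoffRule:
    """Cutoff = end of the calendar month containing the typical onset.

    ``mean_onset_doy`` must come from training folds only.  The DOY-to-
    month mapping uses the non-leap calendar.
    """
    doy = int(np.clip(round(float(mean_onset_doy)), 1, 365))
    month = (dt.date(2007, 1, 1) + dt.timedelta(days=doy - 1)).month
    return CutoffRule(phenophase_id, month)


def _check_window(series: pd.Series, start: pd.Timestamp, cutoff: pd.Timestamp) -> pd.Series:
    if cutoff < start:
        raise ValueError("cutoff before start")
    window = series.loc[start:cutoff]
    expected = len(pd.date_range(start, cutoff, freq="D"))
    if len(window) != expected or window.isna().any():
        raise ValueError(
            f"daily series has gaps in [{start.date()}, {cutoff.date()}]"
        )
    return window


def cum_gdd(
    tmean: pd.Series,
    base_C: float,
    cutoff: pd.Timestamp,
    start: pd.Timestamp | None = None,
) -> float:
    """Cumulative growing degree days: sum of max(tmean - base, 0).

    ``tmean`` is a date-indexed daily series; accumulation runs from
    ``start`` (default Jan 1 of the cutoff's year) through ``cutoff``
    inclusive.
    """
    cutoff = pd.Timestamp(cutoff)
    start = pd.Timestamp(cutoff.year, 1, 1) if start is None else pd.Timestamp(start)
    window = _check_window(tmean, start, cutoff)
    return float(np.maximum(window.to_numpy(dtype=float) - base_C, 0.0).sum())


def cum_gpd(
    precip: pd.Series,
    cutoff: pd.Timestamp,
    start: pd.Timestamp | None = None,
    wet_threshold_mm: float = DEFAULT_WET_THRESHOLD_MM,
) -> int:
    """Cumulative growing precipitation days: count of days with
    ``precip >= wet_threshold_mm`` from ``start`` (default Jan 1) through
    ``cutoff`` inclusive."""
    cutoff = pd.Timestamp(cutoff)
    start = pd.Timestamp(cutoff.year, 1, 1) if start is None else pd.Timestamp(start)
    window = _check_window(precip, start, cutoff)
    return int((window.to_numpy(dtype=float) >= wet_threshold_mm).sum())


def _month_slice(series: pd.Series, year: int, month: int) -> pd.Series:
    last = calendar.monthrange(year, month)[1]
    return _check_window(
        series, pd.Timestamp(year, month, 1), pd.Timestamp(year, month, last)
    )


def monthly_and_seasonal_aggregates(
    tmean: pd.Series,
    precip: pd.Series,
    year: int,
    cutoff: pd.Timestamp,
) -> dict[str, float]:
    """Monthly and seasonal temperature means and precipitation totals.

    Current-year monthly values are emitted only for months wholly on or
    before ``cutoff`` (later months are NaN, handled by training-fold
    imputation downstream).  Previous-December and previous-year seasonal
    values are always computed; missing previous-year data raises.
    """
    cutoff = pd.Timestamp(cutoff)
    prev = year - 1
    try:
        tmean.loc[pd.Timestamp(prev, 1, 1)]
    except KeyError:
        raise ValueError(f"previous year {prev} absent from tmean series") from None

    out: dict[str, float] = {}
    for m in range(1, 13):
        name = _MONTHS[m - 1]
        last = calendar.monthrange(year, m)[1]
        if pd.Timestamp(year, m, last) <= cutoff:
            out[f"met_tmean_{name}"] = float(_month_slice(tmean, year, m).mean())
            out[f"met_prec_{name}"] = float(_month_slice(precip, year, m).sum())
        else:
            out[f"met_tmean_{name}"] = np.nan
            out[f"met_prec_{name}"] = np.nan

    out["met_tmean_dec_prev"] = float(_month_slice(tmean, prev, 12).mean())
    out["met_prec_dec_prev"] = float(_month_slice(precip, prev, 12).sum())

    # previous-year climatological seasons (DJF uses Dec of year-2 when present,
    # otherwise Jan-Feb of the previous year)
    seasons = {"djf": (12, 1, 2), "mam": (3, 4, 5), "jja": (6, 7, 8), "son": (9, 10, 11)}
    for sname, months in seasons.items():
        chunks = []
        for m in months:
            y = prev - 1 if (sname == "djf" and m == 12) else prev
            try:
                chunks.append(_month_slice(tmean, y, m))
            except ValueError:
                if sname == "djf" and m == 12:
                    continue  # Dec of year-2 outside the record
                raise
        out[f"met_tmean_prev_{sname}"] = float(pd.concat(chunks).mean())

    # current winter: Dec(prev)-Feb; current spring: Mar-May
    if pd.Timestamp(year, 2, calendar.monthrange(year, 2)[1]) <= cutoff:
        winter = pd.concat(
            [_month_slice(tmean, prev, 12)]
            + [_month_slice(tmean, year, m) for m in (1, 2)]
        )
        out["met_tmean_winter"] = float(winter.mean())
    else:
        out["met_tmean_winter"] = np.nan
    if pd.Timestamp(year, 5, 31) <= cutoff:
        spring = pd.concat([_month_slice(tmean, year, m) for m in (3, 4, 5)])
        out["met_tmean_spring"] = float(spring.mean())
    else:
        out["met_tmean_spring"] = np.nan
    return out


def assemble_meteo_features(
    tmean: pd.Series,
    precip: pd.Series,
    year: int,
    cutoff: pd.Timestamp,
    wet_threshold_mm: float = DEFAULT_WET_THRESHOLD_MM,
) -> dict[str, float]:
    """All 42 meteorological predictors for one (cell, phenophase, year).

    ``tmean``/``precip`` are daily date-indexed series for the station's
    grid cell, covering at least the previous year through ``cutoff``.
    """
    cutoff = pd.Timestamp(cutoff)
    values = monthly_and_seasonal_aggregates(tmean, precip, year, cutoff)
    for b in GDD_BASES:
        values[f"met_gdd_b{b}"] = cum_gdd(tmean, float(b), cutoff)
    values["met_gpd"] = float(cum_gpd(precip, cutoff, wet_threshold_mm=wet_threshold_mm))
    ordered = {name: values[name] for name in meteo_feature_names()}
    return ordered


def assemble_spatial_features(station: pd.Series) -> dict[str, float]:
    """The 4 spatial predictors of a station (time-invariant)."""
    return {
        "sp_x_km": float(station["x_km"]),
        "sp_y_km": float(station["y_km"]),
        "sp_altitude_m": float(station["altitude_m"]),
        "sp_coast_km": float(station["coast_km"]),
    }
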