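"""Spatial outlier screening of phenophase onset observations.

Ground phenological records are subjective and occasionally grossly wrong
(a misread stage, a transcription slip).  The screen mimics kriging with
external drift in simplified form: a least-squares drift of onset DOY on
projected coordinates and altitude, leave-one-station-out interpolation of
the drift residuals with an exponential distance kernel, and a robust
(MAD-based) threshold on the cross-validated deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ked_screen", "screen_all", "MIN_STATIONS"]

MIN_STATIONS = 8
DEFAULT_RANGE_KM = 100.0
MAD_TO_SD = 1.4826  # consistency factor for normal data


def _drift_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares drift onset ~ 1 + x + y + altitude; returns fitted values."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ coef


def ked_screen(
    obs: pd.DataFrame,
    stations: pd.DataFrame,
    k: float = 3.0,
    range_km: float = DEFAULT_RANGE_KM,
) -> pd.DataFrame:
    """Flag outliers among one phenophase-year's onset observations.

    ``obs`` holds one row per station (columns ``station_id, onset_doy``);
    ``stations`` supplies ``x_km, y_km, altitude_m``.  Returns ``obs``
    plus ``predicted``, ``residual`` (observed - predicted) and ``flag``
    ("ok"/"outlier").  With fewer than ``MIN_STATIONS`` observations the
    screen warns and flags nothing.
    """
    merged = obs.merge(
        stations[["station_id", "x_km", "y_km", "altitude_m"]], on="station_id", how="left"
    )
    if merged[["x_km", "y_km", "altitude_m"]].isna().any().any():
        raise ValueError("observation references an unknown station")
    out = merged.copy()
    n = len(out)
    if n < MIN_STATIONS:
        warnings.warn(
            f"only {n} stations; spatial screen skipped, all records kept",
            stacklevel=2,
        )
        out["predicted"] = np.nan
        out["residual"] = np.nan
        out["flag"] = "ok"
        return out.drop(columns=["x_km", "y_km", "altitude_m"])

    y = out["onset_doy"].to_numpy(dtype=float)
    X = out[["x_km", "y_km", "altitude_m"]].to_numpy(dtype=float)
    drift = _drift_fit(X, y)
    resid = y - drift

    # leave-one-station-out exponential-kernel interpolation of residuals
    coords = out[["x_km", "y_km"]].to_numpy(dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    w = np.exp(-d / range_km)
    np.fill_diagonal(w, 0.0)
    wsum = w.sum(axis=1)
    interp = np.where(wsum > 0, (w @ resid) / np.where(wsum > 0, wsum, 1.0), 0.0)

    predicted = drift + interp
    deviation = y - predicted
    mad = np.median(np.abs(deviation - np.median(deviation)))
    scale = MAD_TO_SD * mad
    if scale == 0:
        flags = np.full(n, "ok", dtype=object)
    else:
        flags = np.where(np.abs(deviation) > k * scale, "outlier", "ok")

    out["predicted"] = predicted
    out["residual"] = deviation
    out["flag"] = flags
    return out.drop(columns=["x_km", "y_km", "altitude_m"])


def screen_all(
    phenology: pd.DataFrame,
    stations: pd.DataFrame,
    k: float = 3.0,
    range_km: float = DEFAULT_RANGE_KM,
) -> pd.DataFrame:
    """Apply :func:`ked_screen` per (phenophase, year) across the record.

    Missing observations pass through untouched with their ``missing``
    flag.  Returns the phenology table with ``predicted``, ``residual``
    and ``qc_flag`` in {ok, outlier, missing}.
    """
    pieces = []
    valid = phenology[phenology["onset_doy"].notna()]
    missing = phenology[phenology["onset_doy"].isna()].copy()
    for (phen, year), grp in valid.groupby(["phenophase_id", "year"]):
        report = ked_screen(grp, stations, k=k, range_km=range_km)
        report["qc_flag"] = report["flag"]
        pieces.append(report.drop(columns=["flag"]))
    if len(missing):
        missing["predicted"] = np.nan
        missing["residual"] = np.nan
        missing["qc_flag"] = "missing"
        pieces.append(missing)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["phenophase_id", "year", "station_id"], ignore_index=True)
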