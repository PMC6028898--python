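"""Synthetic study generator for phenological modelling experiments.

This module emulates the statistical structure of the data sources used in
national-scale plant phenology modelling:

* a registry of phenological monitoring stations on a projected-km grid,
  each attached to a 10x10-km aggregation cell;
* daily gridded mean temperature and precipitation per cell (seasonal
  cycle, meridional gradient, altitudinal lapse, coastal moderation of the
  seasonal amplitude, a common interannual year effect and AR(1) weather
  noise);
* a toy daily binary snow-cover product driven by the weather;
* satellite vegetation-index series (NDVI, EVI, LAI, fPAR) sampled on a
  composite grid from a double-logistic canopy curve, with per-pixel
  biases, pixel-reliability flags 0 (best) to 3 (worst), cloud gaps and
  snow-season suppression;
* ground-truth phenophase onsets: spring phases from a growing-degree-day
  threshold, autumn phases from the canopy curve falling below a fraction
  of its summer maximum, plus rounded Gaussian observer noise.

All generators are deterministic for a fixed seed.  :func:`simulate` wires
the pieces together with named random substreams so that the vegetation
curves seen by the satellite generator are exactly the curves that defined
the autumn ground truth.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phenophase",
    "TruthParams",
    "SyntheticDataset",
    "default_phenophases",
    "gen_stations",
    "gen_daily_meteo",
    "derive_snow",
    "senescence_midpoints",
    "gen_onset_truth",
    "gen_vi",
    "inject_outliers",
    "simulate",
]

VI_VARIABLES = ("NDVI", "EVI", "LAI", "fPAR")

#: physically valid range of each vegetation index
VI_RANGES: Mapping[str, tuple[float, float]] = {
    "NDVI": (-1.0, 1.0),
    "EVI": (-1.0, 1.0),
    "LAI": (0.0, 12.0),
    "fPAR": (0.0, 1.0),
}

#: (winter baseline, summer maximum) of the seasonal profile per index
VI_PROFILES: Mapping[str, tuple[float, float]] = {
    "NDVI": (0.12, 0.85),
    "EVI": (0.10, 0.60),
    "LAI": (0.30, 4.50),
    "fPAR": (0.08, 0.85),
}

AUTUMN_SEARCH_START_DOY = 214  # Aug 1 of a non-leap year; search start for senescence


@dataclass(frozen=True)
class Phenophase:
    """One species/BBCH developmental stage tracked by the network.

    Spring ("thermal") phases are triggered when cumulative growing degree
    days above ``gdd_base_C``, accumulated from Jan 1, reach
    ``gdd_threshold``.  Autumn phases are triggered when the noise-free
    canopy greenness curve falls below ``senescence_threshold`` times its
    summer maximum (searched after Aug 1).
    """

    phenophase_id: str
    season: str  # "spring" | "autumn"
    gdd_base_C: float = 0.0
    gdd_threshold: float | None = None
    senescence_threshold: float | None = None
    obs_noise_sd_days: float = 3.0

    def __post_init__(self) -> None:
        if self.season not in ("spring", "autumn"):
            raise ValueError(f"unknown season {self.season!r}")
        if self.season == "spring":
            if self.gdd_threshold is None or self.gdd_threshold <= 0:
                raise ValueError("spring phenophase needs gdd_threshold > 0")
        else:
            q = self.senescence_threshold
            if q is None or not 0.0 < q < 1.0:
                raise ValueError("autumn phenophase needs 0 < senescence_threshold < 1")
        if self.obs_noise_sd_days < 0:
            raise ValueError("obs_noise_sd_days must be >= 0")


@dataclass(frozen=True)
class TruthParams:
    """Domain-level parameters of the synthetic study region.

    Temperature model (degC): annual mean at the southern sea-level edge
    plus a meridional gradient, an altitudinal lapse, a coastal moderation
    of the seasonal amplitude, a common interannual year effect and AR(1)
    daily weather noise.  Precipitation is Bernoulli(wet) x Gamma (mm).
    """

    t_ann_C: float = 9.0
    seasonal_amplitude_C: float = 10.5
    meridional_gradient_C_per_100km: float = -0.35
    lapse_rate_C_per_km: float = 6.5
    coast_moderation_C: float = 1.5
    coast_decay_km: float = 100.0
    year_effect_sd_C: float = 1.0
    ar1_sd_C: float = 3.0
    ar1_rho: float = 0.7
    wet_day_prob: float = 0.45
    precip_gamma_shape: float = 0.8
    precip_gamma_scale: float = 6.0
    wet_day_threshold_mm: float = 1.0
    snow_melt_mm_per_degC: float = 2.5
    # canopy (double-logistic) curve
    greenup_gdd_base_C: float = 5.0
    greenup_gdd_threshold: float = 170.0
    greenup_rate_per_day: float = 0.09
    senescence_midpoint_doy: float = 275.0
    senescence_rate_per_day: float = 0.06
    senescence_sd_days: float = 8.0
    # satellite sampling
    n_pixels_per_cell: int = 9
    composite_step_days: int = 8
    vi_pixel_sd: float = 0.02
    vi_noise_sd_by_reliability: tuple[float, float, float, float] = (0.01, 0.02, 0.05, 0.10)
    reliability_probs: tuple[float, float, float, float] = (0.50, 0.25, 0.15, 0.10)
    cloud_gap_prob: float = 0.15
    cell_size_km: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet_day_prob must be in [0, 1]")
        if not 0.0 <= self.cloud_gap_prob <= 1.0:
            raise ValueError("cloud_gap_prob must be in [0, 1]")
        if any(sd < 0 for sd in self.vi_noise_sd_by_reliability):
            raise ValueError("noise sds must be >= 0")
        if abs(sum(self.reliability_probs) - 1.0) > 1e-9:
            raise ValueError("reliability_probs must sum to 1")
        if self.senescence_sd_days < 0 or self.year_effect_sd_C < 0 or self.ar1_sd_C < 0:
            raise ValueError("standard deviations must be >= 0")


def default_phenophases() -> tuple[Phenophase, ...]:
    """Six default phenophases spanning earliest spring to late autumn.

    Thresholds were calibrated once against the noise-free default climate
    so mean onsets land near typical Central-European dates (hazel
    flowering ~DOY 70, birch leaf unfolding ~110, lilac flowering ~130,
    lime flowering ~180, birch leaf colouring ~272, birch leaf fall ~300).
    """
    return (
        Phenophase("hazel_flowering", "spring", gdd_base_C=0.0, gdd_threshold=30.0),
        Phenophase("birch_leaf_unfolding", "spring", gdd_base_C=3.0, gdd_threshold=90.0),
        Phenophase("lilac_flowering", "spring", gdd_base_C=5.0, gdd_threshold=150.0),
        Phenophase("lime_flowering", "spring", gdd_base_C=6.0, gdd_threshold=450.0),
        Phenophase("birch_leaf_coloring", "autumn", senescence_threshold=0.55),
        Phenophase("birch_leaf_fall", "autumn", senescence_threshold=0.18),
    )


# ---------------------------------------------------------------------------
# random substreams

_STREAMS = {
    "stations": 0,
    "meteo": 1,
    "senescence": 2,
    "onset": 3,
    "vi": 4,
    "outliers": 5,
}


def _rng(seed: int, key: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(key),)))


# ---------------------------------------------------------------------------
# stations


def gen_stations(
    n: int,
    extent: tuple[float, float] = (650.0, 650.0),
    altitude_range: tuple[float, float] = (0.0, 400.0),
    seed: int = 0,
    cell_size_km: float = 10.0,
) -> pd.DataFrame:
    """Generate a registry of ``n`` monitoring stations.

    Stations are uniform on the ``extent`` rectangle (projected km); the
    coast is the northern edge, so ``coast_km = extent_height - y_km``.
    Each station belongs to exactly one ``cell_size_km`` square cell.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    width, height = float(extent[0]), float(extent[1])
    if width <= 0 or height <= 0:
        raise ValueError("extent must be non-degenerate")
    lo, hi = altitude_range
    if hi < lo:
        raise ValueError("altitude_range reversed")
    rng = _rng(seed, _STREAMS["stations"])
    x = rng.uniform(0.0, width, n)
    y = rng.uniform(0.0, height, n)
    alt = rng.uniform(lo, hi, n)
    ix = np.minimum((x // cell_size_km).astype(int), int(width // cell_size_km))
    iy = np.minimum((y // cell_size_km).astype(int), int(height // cell_size_km))
    return pd.DataFrame(
        {
            "station_id": [f"st{i:03d}" for i in range(n)],
            "x_km": x,
            "y_km": y,
            "altitude_m": alt,
            "coast_km": height - y,
            "cell_id": [f"c{i:03d}_{j:03d}" for i, j in zip(ix, iy)],
        }
    )


def _cell_table(stations: pd.DataFrame) -> pd.DataFrame:
    """Per-cell covariates (centroid of member stations)."""
    return stations.groupby("cell_id", as_index=True)[
        ["x_km", "y_km", "altitude_m", "coast_km"]
    ].mean()


# ---------------------------------------------------------------------------
# daily weather


def _climatology(doy: np.ndarray, year_len: np.ndarray, cell: pd.Series, params: TruthParams) -> np.ndarray:
    amp = params.seasonal_amplitude_C - params.coast_moderation_C * np.exp(
        -cell["coast_km"] / params.coast_decay_km
    )
    base = (
        params.t_ann_C
        + params.meridional_gradient_C_per_100km * cell["y_km"] / 100.0
        - params.lapse_rate_C_per_km * cell["altitude_m"] / 1000.0
    )
    return base - amp * np.cos(2.0 * np.pi * (doy - 15.0) / year_len)


def gen_daily_meteo(
    stations: pd.DataFrame,
    years: Sequence[int],
    params: TruthParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily mean temperature and precipitation per aggregation cell.

    Returns a long-format frame with columns
    ``cell_id, date, variable, value`` where ``variable`` is ``tmean_C``
    or ``precip_mm``; coverage is every calendar day (leap days included)
    of ``years``.
    """
    years = sorted(int(y) for y in years)
    if not years:
        raise ValueError("years must be non-empty")
    params = params or TruthParams()
    cells = _cell_table(stations)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    year = dates.year.to_numpy()
    year_len = np.where(dates.is_leap_year, 366.0, 365.0)

    rng = _rng(seed, _STREAMS["meteo"])
    year_effect = dict(zip(years, rng.normal(0.0, params.year_effect_sd_C, len(years))))
    yeff = np.array([year_effect[y] for y in year])

    frames = []
    n = len(dates)
    innov_sd = params.ar1_sd_C * np.sqrt(max(1.0 - params.ar1_rho**2, 0.0))
    for cell_id, cell in cells.iterrows():
        clim = _climatology(doy, year_len, cell, params)
        eps = rng.normal(0.0, innov_sd, n)
        noise = np.empty(n)
        prev = rng.normal(0.0, params.ar1_sd_C) if params.ar1_sd_C > 0 else 0.0
        rho = params.ar1_rho
        for i in range(n):
            prev = rho * prev + eps[i]
            noise[i] = prev
        tmean = clim + yeff + noise

        wet = rng.random(n) < params.wet_day_prob
        if params.precip_gamma_shape > 0:
            amounts = rng.gamma(params.precip_gamma_shape, params.precip_gamma_scale, n)
        else:
            amounts = np.zeros(n)
        precip = np.where(wet, amounts, 0.0)

        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "date": np.concatenate([dates, dates]),
                    "variable": np.repeat(["tmean_C", "precip_mm"], n),
                    "value": np.concatenate([tmean, precip]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _pivot_meteo(meteo: pd.DataFrame, variable: str) -> pd.DataFrame:
    """date x cell wide frame for one variable; validates daily contiguity."""
    sub = meteo[meteo["variable"] == variable]
    if sub.empty:
        raise ValueError(f"no {variable!r} rows in meteo frame")
    wide = sub.pivot_table(index="date", columns="cell_id", values="value")
    wide.index = pd.DatetimeIndex(wide.index)
    wide = wide.sort_index()
    full = pd.date_range(wide.index[0], wide.index[-1], freq="D")
    if len(full) != len(wide.index) or wide.isna().any().any():
        raise ValueError(f"{variable} series is not contiguous daily per cell")
    return wide


def derive_snow(meteo: pd.DataFrame, params: TruthParams | None = None) -> pd.DataFrame:
    """Binary daily snow cover from a toy snowpack water balance.

    Pack gains the day's precipitation when ``tmean < 0`` and loses
    ``snow_melt_mm_per_degC * max(tmean, 0)`` mm otherwise;
    ``snow_01 = 1`` while the pack is positive.
    """
    params = params or TruthParams()
    tmean = _pivot_meteo(meteo, "tmean_C")
    precip = _pivot_meteo(meteo, "precip_mm")
    if not tmean.index.equals(precip.index) or list(tmean.columns) != list(precip.columns):
        raise ValueError("tmean and precip grids are not aligned")
    out = {}
    for cell in tmean.columns:
        t = tmean[cell].to_numpy()
        p = precip[cell].to_numpy()
        pack = 0.0
        snow = np.zeros(len(t), dtype=int)
        for i in range(len(t)):
            if t[i] < 0.0 and p[i] > 0.0:
                pack += p[i]
            else:
                pack = max(pack - params.snow_melt_mm_per_degC * max(t[i], 0.0), 0.0)
            snow[i] = 1 if pack > 0.0 else 0
        out[cell] = snow
    wide = pd.DataFrame(out, index=tmean.index)
    long = wide.reset_index().melt(id_vars="date", var_name="cell_id", value_name="value")
    long["variable"] = "snow_01"
    return long[["cell_id", "date", "variable", "value"]].sort_values(
        ["cell_id", "date"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# canopy curve and ground truth


def senescence_midpoints(
    cell_ids: Sequence[str],
    years: Sequence[int],
    params: TruthParams,
    seed: int,
) -> pd.DataFrame:
    """Senescence midpoint (DOY) per (cell, year).

    Drawn as ``senescence_midpoint_doy + N(0, senescence_sd_days)`` from a
    dedicated substream: the autumn signal is deliberately independent of
    the weather so that only vegetation observations can explain it.
    """
    cell_ids = sorted(cell_ids)
    years = sorted(int(y) for y in years)
    rng = _rng(seed, _STREAMS["senescence"])
    draws = rng.normal(
        params.senescence_midpoint_doy, params.senescence_sd_days, (len(cell_ids), len(years))
    )
    return pd.DataFrame(draws, index=pd.Index(cell_ids, name="cell_id"), columns=years)


def _greenup_midpoints(tmean: pd.DataFrame, params: TruthParams) -> pd.DataFrame:
    """Green-up midpoint DOY per (cell, year): day cumulative GDD reaches threshold."""
    years = sorted(tmean.index.year.unique())
    out = pd.DataFrame(index=pd.Index(tmean.columns, name="cell_id"), columns=years, dtype=float)
    for y in years:
        block = tmean[tmean.index.year == y]
        gdd = np.maximum(block.to_numpy() - params.greenup_gdd_base_C, 0.0).cumsum(axis=0)
        reached = gdd >= params.greenup_gdd_threshold
        first = np.where(reached.any(axis=0), reached.argmax(axis=0) + 1, len(block) // 2)
        out[y] = first.astype(float)
    return out


def _canopy_curve(
    n_days: int, m1: float, m2: float, params: TruthParams
) -> np.ndarray:
    """Normalized canopy greenness, product of green-up and senescence logistics."""
    d = np.arange(1, n_days + 1, dtype=float)
    g1 = 1.0 / (1.0 + np.exp(-params.greenup_rate_per_day * (d - m1)))
    g2 = 1.0 / (1.0 + np.exp(params.senescence_rate_per_day * (d - m2)))
    return g1 * g2


def gen_onset_truth(
    stations: pd.DataFrame,
    meteo: pd.DataFrame,
    snow: pd.DataFrame | None,
    params: TruthParams,
    phenophases: Sequence[Phenophase],
    seed: int = 0,
    midpoints: pd.DataFrame | None = None,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Phenophase onset observations per (station, phenophase, year).

    Spring onsets come from the GDD threshold process, autumn onsets from
    the canopy curve crossing ``senescence_threshold x summer maximum``
    after Aug 1; rounded Gaussian observer noise is added per station.
    Unreached thresholds yield ``qc_flag = "missing"`` records.
    ``snow`` is accepted for interface symmetry but does not alter onsets.
    ``years`` defaults to every year covered by ``meteo`` (pass the study
    years explicitly when the record includes a spin-up year).
    """
    tmean = _pivot_meteo(meteo, "tmean_C")
    years = sorted(tmean.index.year.unique()) if years is None else sorted(years)
    if midpoints is None:
        midpoints = senescence_midpoints(list(tmean.columns), years, params, seed)
    m1 = _greenup_midpoints(tmean, params)
    rng = _rng(seed, _STREAMS["onset"])

    records = []
    stations_sorted = stations.sort_values("station_id")
    for phen in phenophases:
        # cell-level noise-free onset per year
        cell_onsets: dict[tuple[str, int], float] = {}
        for cell in tmean.columns:
            for y in years:
                block = tmean.loc[tmean.index.year == y, cell].to_numpy()
                n_days = len(block)
                if phen.season == "spring":
                    cum = np.maximum(block - phen.gdd_base_C, 0.0).cumsum()
                    hit = cum >= phen.gdd_threshold
                    onset = float(hit.argmax() + 1) if hit.any() else np.nan
                else:
                    curve = _canopy_curve(n_days, m1.loc[cell, y], midpoints.loc[cell, y], params)
                    start = AUTUMN_SEARCH_START_DOY + (1 if n_days == 366 else 0)
                    tail = curve[start - 1 :]
                    hit = tail < phen.senescence_threshold * curve.max()
                    onset = float(start + hit.argmax()) if hit.any() else np.nan
                cell_onsets[(cell, y)] = onset
        for _, st in stations_sorted.iterrows():
            for y in years:
                onset = cell_onsets[(st["cell_id"], y)]
                noise = rng.normal(0.0, phen.obs_noise_sd_days)
                if np.isnan(onset):
                    records.append((st["station_id"], phen.phenophase_id, y, np.nan, "missing"))
                else:
                    n_days = 366 if calendar.isleap(y) else 365
                    doy = int(np.clip(round(onset + noise), 1, n_days))
                    records.append((st["station_id"], phen.phenophase_id, y, doy, "ok"))
    return pd.DataFrame(
        records, columns=["station_id", "phenophase_id", "year", "onset_doy", "qc_flag"]
    )


# ---------------------------------------------------------------------------
# satellite vegetation indices


def gen_vi(
    stations: pd.DataFrame,
    meteo: pd.DataFrame,
    snow: pd.DataFrame,
    onsets: pd.DataFrame | None,
    params: TruthParams,
    seed: int = 0,
    midpoints: pd.DataFrame | None = None,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Pixel-level vegetation-index observations on the composite grid.

    Each cell holds ``n_pixels_per_cell`` synthetic pixels sampled every
    ``composite_step_days`` days.  Values follow the cell's canopy curve
    scaled to the index profile, with a fixed per-pixel bias, reliability
    flags drawn from ``reliability_probs`` and additive noise whose sd
    grows with the flag; snow days are forced to the winter baseline;
    observations are dropped entirely with probability ``cloud_gap_prob``.
    Returns columns ``cell_id, pixel_id, date, variable, value,
    reliability`` (missing observations are absent rows).
    """
    tmean = _pivot_meteo(meteo, "tmean_C")
    snow_wide = snow.pivot_table(index="date", columns="cell_id", values="value")
    snow_wide.index = pd.DatetimeIndex(snow_wide.index)
    years = sorted(tmean.index.year.unique()) if years is None else sorted(years)
    if midpoints is None:
        midpoints = senescence_midpoints(list(tmean.columns), years, params, seed)
    m1 = _greenup_midpoints(tmean, params)
    rng = _rng(seed, _STREAMS["vi"])

    step = int(params.composite_step_days)
    n_pix = int(params.n_pixels_per_cell)
    frames = []
    for cell in tmean.columns:
        pixel_bias = rng.normal(0.0, params.vi_pixel_sd, n_pix)  # in units of index amplitude
        for y in years:
            n_days = 366 if calendar.isleap(y) else 365
            doys = np.arange(1, 362, step)
            dates = pd.to_datetime(f"{y}-01-01") + pd.to_timedelta(doys - 1, unit="D")
            curve = _canopy_curve(n_days, m1.loc[cell, y], midpoints.loc[cell, y], params)[doys - 1]
            snow_flag = snow_wide.loc[dates, cell].to_numpy() > 0
            nd = len(doys)
            flags = rng.choice(4, size=(n_pix, nd), p=list(params.reliability_probs))
            gaps = rng.random((n_pix, nd)) < params.cloud_gap_prob
            white = rng.standard_normal((n_pix, nd, len(VI_VARIABLES)))
            for k, var in enumerate(VI_VARIABLES):
                w, s = VI_PROFILES[var]
                amp = s - w
                base = np.where(snow_flag, w, w + amp * curve)  # (nd,)
                sd = np.asarray(params.vi_noise_sd_by_reliability)[flags] * amp
                vals = base[None, :] + pixel_bias[:, None] * amp + sd * white[:, :, k]
                lo, hi = VI_RANGES[var]
                vals = np.clip(vals, lo, hi)
                keep = ~gaps
                pix_idx, date_idx = np.nonzero(keep)
                frames.append(
                    pd.DataFrame(
                        {
                            "cell_id": cell,
                            "pixel_id": pix_idx,
                            "date": dates[date_idx],
                            "variable": var,
                            "value": vals[keep],
                            "reliability": flags[keep],
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            columns=["cell_id", "pixel_id", "date", "variable", "value", "reliability"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# QC fixtures


def inject_outliers(
    obs: pd.DataFrame,
    rate: float,
    shift_days: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Shift a Bernoulli(rate) subset of onsets by +-``shift_days``.

    Returns the perturbed copy and a boolean truth-flag vector aligned to
    the rows of ``obs``; only non-missing observations are eligible.
    Perturbed ``onset_doy`` is clipped to [1, 366].
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = _rng(seed, _STREAMS["outliers"])
    out = obs.copy(deep=True)
    eligible = out["onset_doy"].notna().to_numpy()
    hit = (rng.random(len(out)) < rate) & eligible
    signs = np.where(rng.random(len(out)) < 0.5, -1.0, 1.0)
    shifted = out["onset_doy"].to_numpy(dtype=float) + signs * shift_days
    out.loc[hit, "onset_doy"] = np.clip(shifted[hit], 1, 366)
    return out, hit


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticDataset:
    """All artefacts of one simulated study, plus the truth that made them."""

    stations: pd.DataFrame
    meteo: pd.DataFrame
    snow: pd.DataFrame
    phenology: pd.DataFrame
    vi: pd.DataFrame
    params: TruthParams
    phenophases: tuple[Phenophase, ...]
    midpoints: pd.DataFrame
    seed: int
    years: tuple[int, ...] = ()


def simulate(
    n_stations: int = 30,
    years: Iterable[int] = range(2007, 2015),
    params: TruthParams | None = None,
    phenophases: Sequence[Phenophase] | None = None,
    seed: int = 0,
    extent: tuple[float, float] = (650.0, 650.0),
    altitude_range: tuple[float, float] = (0.0, 400.0),
) -> SyntheticDataset:
    """Run every generator with consistent substreams of ``seed``."""
    params = params or TruthParams()
    phenophases = tuple(phenophases or default_phenophases())
    years = tuple(sorted(int(y) for y in years))
    stations = gen_stations(
        n_stations, extent, altitude_range, seed=seed, cell_size_km=params.cell_size_km
    )
    # the weather record starts one spin-up year early so previous-year
    # predictors exist for the first study year
    meteo_years = (years[0] - 1,) + years
    meteo = gen_daily_meteo(stations, meteo_years, params, seed=seed)
    snow = derive_snow(meteo, params)
    cells = sorted(stations["cell_id"].unique())
    midpoints = senescence_midpoints(cells, years, params, seed)
    phenology = gen_onset_truth(
        stations, meteo, snow, params, phenophases, seed=seed, midpoints=midpoints, years=years
    )
    vi = gen_vi(
        stations, meteo, snow, phenology, params, seed=seed, midpoints=midpoints, years=years
    )
    return SyntheticDataset(
        stations, meteo, snow, phenology, vi, params, phenophases, midpoints, seed, years
    )
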