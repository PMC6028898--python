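"""Readers and writers for the pipeline's on-disk formats.

Everything is plain CSV with fixed, documented column names; daily gridded
series additionally round-trip through NetCDF3 (via xarray's scipy
backend) for interoperability with gridded-climate tooling.

Formats
-------
stations.csv   station_id, x_km, y_km, altitude_m, coast_km, cell_id
phenology.csv  station_id, phenophase_id, year, onset_doy, qc_flag
meteo.csv      cell_id, date, variable (tmean_C | precip_mm), value
snow.csv       cell_id, date, variable (snow_01), value
vi.csv         cell_id, pixel_id, date, variable (NDVI|EVI|LAI|fPAR),
               value, reliability
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_stations", "read_stations",
    "write_phenology", "read_phenology",
    "write_meteo", "read_meteo",
    "write_snow", "read_snow",
    "write_vi", "read_vi",
]


def write_stations(stations: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    stations.to_csv(path, index=False)
    return path


def read_stations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"station_id", "x_km", "y_km", "altitude_m", "coast_km", "cell_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stations file missing columns: {sorted(missing)}")
    return df


def write_phenology(phenology: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["station_id", "phenophase_id", "year", "onset_doy", "qc_flag"]
    extra = [c for c in phenology.columns if c not in cols]
    phenology[cols + extra].to_csv(path, index=False)
    return path


def read_phenology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["year"] = df["year"].astype(int)
    return df


def _write_long_daily(df: pd.DataFrame, path: Path) -> Path:
    if path.suffix == ".nc":
        import xarray as xr

        wide = df.pivot_table(index="date", columns=["cell_id", "variable"], values="value")
        ds = xr.Dataset(
            {
                var: (("date", "cell_id"), wide.xs(var, axis=1, level="variable").to_numpy())
                for var in df["variable"].unique()
            },
            coords={
                "date": pd.DatetimeIndex(wide.index),
                "cell_id": list(wide.columns.levels[0]),
            },
        )
        ds.to_netcdf(path, engine="scipy")
        return path
    df.to_csv(path, index=False, date_format="%Y-%m-%d")
    return path


def _read_long_daily(path: Path) -> pd.DataFrame:
    if path.suffix == ".nc":
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        frames = []
        for var in ds.data_vars:
            frames.append(
                ds[var]
                .to_dataframe(name="value")
                .reset_index()
                .assign(variable=var)[["cell_id", "date", "variable", "value"]]
            )
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.read_csv(path)
    out["date"] = pd.to_datetime(out["date"])
    return out


def write_meteo(meteo: pd.DataFrame, path: str | Path) -> Path:
    return _write_long_daily(meteo, Path(path))


def read_meteo(path: str | Path) -> pd.DataFrame:
    return _read_long_daily(Path(path))


def write_snow(snow: pd.DataFrame, path: str | Path) -> Path:
    return _write_long_daily(snow, Path(path))


def read_snow(path: str | Path) -> pd.DataFrame:
    return _read_long_daily(Path(path))


def write_vi(vi: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    vi.to_csv(path, index=False, date_format="%Y-%m-%d")
    return path


def read_vi(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df
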