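"""Fold-aware assembly of the full 115-column predictor table.

One row per (station, year) for a given phenophase: 4 spatial + 42
meteorological + 69 satellite predictors, every value computable from data
dated on or before the phenophase cutoff.  Cutoff rules and normalization
histories are supplied per cross-validation fold so that no test-year
information leaks into training artefacts; expensive intermediates (daily
cumulative degree days, smoothed VI series) are cached across folds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .meteo_features import (
    CutoffRule,
    assemble_meteo_features,
    assemble_spatial_features,
    meteo_feature_names,
    spatial_feature_names,
)
from .satellite_features import (
    VICellCache,
    assemble_modis_features,
    modis_feature_names,
    snow_feature_names,
)
from .synthetic_data import SyntheticDataset, _pivot_meteo

__all__ = ["FeatureBuilder", "all_feature_names", "feature_categories"]


def all_feature_names() -> list[str]:
    """The 115 predictor names: 4 spatial, 42 meteorological, 69 satellite."""
    return (
        spatial_feature_names()
        + meteo_feature_names()
        + modis_feature_names()
        + snow_feature_names()
    )


def feature_categories() -> dict[str, str]:
    """Category tag per predictor: spatial | meteo | modis."""
    cats: dict[str, str] = {}
    for name in spatial_feature_names():
        cats[name] = "spatial"
    for name in meteo_feature_names():
        cats[name] = "meteo"
    for name in modis_feature_names() + snow_feature_names():
        cats[name] = "modis"
    return cats


class FeatureBuilder:
    """Builds per-(station, year) predictor rows from the raw daily data."""

    def __init__(
        self,
        stations: pd.DataFrame,
        meteo: pd.DataFrame,
        snow: pd.DataFrame,
        vi: pd.DataFrame,
    ):
        self.stations = stations.set_index("station_id")
        self._tmean = _pivot_meteo(meteo, "tmean_C")
        self._precip = _pivot_meteo(meteo, "precip_mm")
        self.vicache = VICellCache(vi, snow)
        self._meteo_cache: dict[tuple[str, int, int], dict[str, float]] = {}
        self._modis_cache: dict[tuple, dict[str, float]] = {}

    @classmethod
    def from_dataset(cls, data: SyntheticDataset) -> "FeatureBuilder":
        return cls(data.stations, data.meteo, data.snow, data.vi)

    def _meteo_row(self, cell: str, year: int, rule: CutoffRule) -> dict[str, float]:
        key = (cell, year, rule.month)
        if key not in self._meteo_cache:
            self._meteo_cache[key] = assemble_meteo_features(
                self._tmean[cell], self._precip[cell], year, rule.cutoff_date(year)
            )
        return self._meteo_cache[key]

    def _modis_row(
        self, cell: str, year: int, rule: CutoffRule, train_years: tuple[int, ...]
    ) -> dict[str, float]:
        key = (cell, year, rule.month, train_years)
        if key not in self._modis_cache:
            self._modis_cache[key] = assemble_modis_features(
                self.vicache, cell, year, rule, train_years
            )
        return self._modis_cache[key]

    def feature_row(
        self,
        station_id: str,
        year: int,
        rule: CutoffRule,
        train_years: Sequence[int],
    ) -> dict[str, float]:
        station = self.stations.loc[station_id]
        cell = station["cell_id"]
        row = assemble_spatial_features(station)
        row.update(self._meteo_row(cell, int(year), rule))
        row.update(self._modis_row(cell, int(year), rule, tuple(sorted(train_years))))
        return row

    def feature_table(
        self,
        obs: pd.DataFrame,
        rule: CutoffRule,
        train_years: Sequence[int],
    ) -> pd.DataFrame:
        """Predictor table for the (station_id, year) rows of ``obs``.

        ``train_years`` feeds the location-normalization history; pass the
        fold's training years (for an all-data fit, every study year).
        """
        rows = [
            self.feature_row(r.station_id, int(r.year), rule, train_years)
            for r in obs.itertuples()
        ]
        table = pd.DataFrame(rows, columns=all_feature_names())
        table.insert(0, "station_id", obs["station_id"].to_numpy())
        table.insert(1, "year", obs["year"].to_numpy(dtype=int))
        return table


def write_features(
    table: pd.DataFrame, phenophase_id: str, outdir: str | Path
) -> tuple[Path, Path]:
    """Write features.csv plus the sidecar JSON category map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"features_{phenophase_id}.csv"
    table.to_csv(csv_path, index=False)
    map_path = outdir / "feature_categories.json"
    map_path.write_text(json.dumps(feature_categories(), indent=1))
    return csv_path, map_path
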