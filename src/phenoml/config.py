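"""Run configuration: one YAML document drives the whole pipeline.

All randomness flows from the single root ``seed`` through named
substreams; a run writes its resolved configuration next to its outputs so
any result can be regenerated byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .model_suite import TECHNIQUES
from .synthetic_data import Phenophase, TruthParams, default_phenophases

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    years: list[int] = field(default_factory=lambda: list(range(2007, 2015)))
    n_stations: int = 30
    extent: tuple[float, float] = (650.0, 650.0)
    altitude_range: tuple[float, float] = (0.0, 400.0)
    phenophases: list[dict[str, Any]] | None = None  # None -> package defaults
    truth_params: dict[str, Any] = field(default_factory=dict)
    techniques: list[str] = field(default_factory=lambda: list(TECHNIQUES))
    groups: list[str] = field(default_factory=lambda: ["meteo", "modis", "boruta", "all"])
    grids: dict[str, dict[str, list]] = field(
        default_factory=lambda: {
            "gbm": {"n_estimators": [200], "max_depth": [3], "learning_rate": [0.05]}
        }
    )
    inner_cv: int = 5
    screening: dict[str, Any] = field(default_factory=lambda: {"max_iter": 50, "alpha": 0.01})
    qc_k: float = 3.0
    qc_range_km: float = 100.0
    outdir: str = "runs/default"

    def truth(self) -> TruthParams:
        return TruthParams(**self.truth_params)

    def phenophase_objects(self) -> tuple[Phenophase, ...]:
        if self.phenophases is None:
            return default_phenophases()
        return tuple(Phenophase(**spec) for spec in self.phenophases)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["altitude_range"] = list(self.altitude_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("extent", "altitude_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
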