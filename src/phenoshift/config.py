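"""Pipeline configuration: dataclasses with YAML round-trip.

Every field has an explicit default and the full (defaults included)
configuration is echoed into the run manifest, so no setting is silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class GridConfig:
    bbox: tuple[float, float, float, float] = (5.0, 45.0, 15.0, 55.0)
    cell_size: float = 50_000.0


@dataclass
class PhenometricsConfig:
    q: float = 0.5
    n_bootstrap: int = 250
    min_count: int = 25


@dataclass
class InterpolationConfig:
    enabled: bool = True
    param_grid: dict | None = None  # None -> library default grid
    cv_folds: int = 5


@dataclass
class ClimateConfig:
    base_temp: float = 5.0
    enabled: bool = True


@dataclass
class InferenceConfig:
    reference_year: int | None = None  # None -> first year present
    observed_only: bool = True
    season_threshold_doy: float = 172.0


@dataclass
class SyntheticConfig:
    """Synthetic-data study conditions used when mode == 'synthetic'."""

    n_cols: int = 20
    n_rows: int = 20
    years: tuple[int, ...] = (2020, 2021)
    surface: dict = field(default_factory=dict)  # TrueSurface overrides
    effort: dict = field(default_factory=dict)  # EffortModel overrides
    climate: dict = field(default_factory=dict)  # SyntheticClimate overrides
    warming_offset_first_year: float = 2.0  # first year warmer, like 2020


@dataclass
class PathsConfig:
    observations: tuple[str, ...] = ()
    elevation: str | None = None
    temperature: dict = field(default_factory=dict)  # year -> NetCDF path
    out_dir: str = "results"


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # 'synthetic' or 'files'
    seed: int = 0
    grid: GridConfig = field(default_factory=GridConfig)
    phenometrics: PhenometricsConfig = field(default_factory=PhenometricsConfig)
    interpolation: InterpolationConfig = field(default_factory=InterpolationConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sub = {
            "grid": GridConfig,
            "phenometrics": PhenometricsConfig,
            "interpolation": InterpolationConfig,
            "climate": ClimateConfig,
            "inference": InferenceConfig,
            "synthetic": SyntheticConfig,
            "paths": PathsConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sub:
                kwargs[key] = sub[key](**(value or {}))
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        # YAML round-trips tuples as lists; normalise back
        cfg.grid.bbox = tuple(cfg.grid.bbox)
        cfg.synthetic.years = tuple(cfg.synthetic.years)
        cfg.paths.observations = tuple(cfg.paths.observations)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
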