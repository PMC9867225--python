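"""Pipeline configuration schema.

Everything the pipeline does is a pure function of one :class:`PipelineConfig`
plus one root seed.  The schema is strict: unknown keys are rejected so a typo
in a YAML file fails loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Independent named random substream derived from the root seed.

    The derived key is ``crc32(name) & 0x7FFFFFFF`` so every seed stays a
    small nonnegative 31-bit integer.
    """
    return np.random.default_rng([int(root_seed), zlib.crc32(name.encode()) & 0x7FFFFFFF])


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    n_rows: int = 30
    n_cols: int = 30
    cell_size_m: float = 5000.0
    fine_factor: int = 10       # county geometry resolution (sub-cells per cell side)
    supersample: int = 5        # raster pixels per cell side
    n_counties: int = 12


class ClusterSpec(_Strict):
    """A planted circular anomaly in the latent health field (cell units)."""

    row: float
    col: float
    radius: float = 4.0
    amplitude: float = 2.0      # z-units; positive = high-health hot spot


class TruthConfig(_Strict):
    """Embedded structure of the synthetic scenario (recoverable by tests)."""

    correlation_range: float = 2.0   # Gaussian smoothing radius, in cells
    clusters: list[ClusterSpec] = Field(
        default_factory=lambda: [
            ClusterSpec(row=9.0, col=9.0, radius=4.0, amplitude=2.0),
            ClusterSpec(row=22.0, col=21.0, radius=4.0, amplitude=-2.0),
        ]
    )
    npp_mean: float = 500.0          # gC/m^2/yr
    npp_sd: float = 80.0
    npp_trend: float = -2.0          # per year
    ndvi_mean: float = 0.62
    ndvi_sd: float = 0.08
    ndvi_trend: float = -0.001
    cultivated_mean: float = 0.55    # cultivated fraction of a cell
    cultivated_sd: float = 0.18


class IndicatorSpec(_Strict):
    """How one raw panel indicator is synthesized and later disaggregated."""

    code: str
    mean: float
    trend: float = 0.0               # additive change per calendar year
    noise: float = 0.0               # sd of county-year noise
    county_sd: float = 0.15          # sd of the multiplicative county effect
    direction: Literal["+", "-"]
    variant: Literal["total", "cultivated"]
    kind: Literal["nonneg", "percent", "free"] = "nonneg"

    @model_validator(mode="after")
    def _check(self):
        if self.noise < 0 or self.county_sd < 0:
            raise ValueError(f"negative noise scale for {self.code}")
        return self


class CropSpec(_Strict):
    name: str
    area_share: float                # fraction of total grain area
    yield_kg_per_hm2: float
    price_yuan_per_kg: float


class WeightingConfig(_Strict):
    variance_target: float = 0.80
    loading_threshold: float = 0.5
    fixed_weights: Optional[dict[str, float]] = None  # bypass PCA/CRITIC


class SpatialConfig(_Strict):
    moran_scheme: Literal["queen", "rook", "distance"] = "queen"
    gistar_distance_factor: float = 1.5   # band = factor x cell size
    n_permutations: int = 999
    alpha: float = 0.05


class ClassificationConfig(_Strict):
    n_classes: int = 5
    pooled: bool = True              # one Jenks fit over all cell-years


class PipelineConfig(_Strict):
    grid: GridConfig = Field(default_factory=GridConfig)
    truth: TruthConfig = Field(default_factory=TruthConfig)
    years: list[int] = Field(default_factory=lambda: [2000, 2005, 2010, 2015, 2019])
    indicators: list[IndicatorSpec] = Field(default_factory=lambda: default_indicator_specs())
    crops: list[CropSpec] = Field(default_factory=lambda: default_crops())
    weighting: WeightingConfig = Field(default_factory=WeightingConfig)
    spatial: SpatialConfig = Field(default_factory=SpatialConfig)
    classification: ClassificationConfig = Field(default_factory=ClassificationConfig)
    seed: int = 0
    write_geojson: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.grid.n_counties < 1:
            raise ValueError("need at least one county")
        if self.grid.n_rows * self.grid.n_cols < self.grid.n_counties:
            raise ValueError("more counties than grid cells")
        if len(self.years) < 1:
            raise ValueError("need at least one year")
        codes = [s.code for s in self.indicators]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate indicator codes in config")
        return self


def default_indicator_specs() -> list[IndicatorSpec]:
    """Raw panel indicators of the default scenario.

    Magnitudes are plausible for an intensively farmed alluvial plain;
    pressure indicators rise over time while several state/response
    indicators decline, so the composite health of the default scenario
    drifts downward across the study years.
    """
    rows = [
        # code   mean   trend   noise  direction variant       kind
        ("D1",   420.0,  3.0,   30.0,  "-", "total",      "nonneg"),   # population density, persons/km^2
        ("D4",   900.0,  60.0,  120.0, "-", "total",      "nonneg"),   # economic density, 1e4 yuan/km^2
        ("D5",   55.0,   0.30,  3.0,   "-", "cultivated", "percent"),  # land reclamation rate, %
        ("D6",   11.0,   0.12,  0.8,   "-", "cultivated", "nonneg"),   # pesticide intensity, kg/hm^2
        ("D7",   320.0,  4.0,   20.0,  "-", "cultivated", "nonneg"),   # fertilizer intensity, kg/hm^2
        ("D14",  28.0,  -0.35,  2.0,   "+", "total",      "percent"),  # agricultural output share, %
        ("D15",  45.0,  -0.60,  3.0,   "+", "total",      "percent"),  # agricultural employee share, %
        ("D17",  0.085, -5e-4,  0.006, "+", "cultivated", "nonneg"),   # per capita cultivated land, hm^2
        ("D19",  480.0, -2.0,   25.0,  "+", "cultivated", "nonneg"),   # grain per capita, kg
        ("D20",  4000.0, 450.0, 300.0, "+", "cultivated", "nonneg"),   # farmer net income per capita, yuan
        ("D21",  5.5,    0.15,  0.4,   "+", "cultivated", "nonneg"),   # mechanization level, kW/hm^2
        ("D22",  4.0,    0.08,  0.3,   "+", "cultivated", "nonneg"),   # agricultural power intensity, kW/hm^2
    ]
    return [
        IndicatorSpec(code=c, mean=m, trend=t, noise=n, direction=d, variant=v, kind=k)
        for c, m, t, n, d, v, k in rows
    ]


def default_crops() -> list[CropSpec]:
    """Aggregate grain-crop mix for the ecosystem-service-value baseline."""
    return [
        CropSpec(name="rice", area_share=0.55, yield_kg_per_hm2=7100.0, price_yuan_per_kg=2.80),
        CropSpec(name="wheat", area_share=0.25, yield_kg_per_hm2=5600.0, price_yuan_per_kg=2.50),
        CropSpec(name="maize", area_share=0.20, yield_kg_per_hm2=6300.0, price_yuan_per_kg=2.90),
    ]


def load_config(path: str | Path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig.model_validate(raw)
    except (yaml.YAMLError, ValidationError) as exc:
        raise ConfigurationError(str(exc)) from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
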