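"""Seeded synthetic study scenarios.

Emulates the four data products the evaluation pipeline consumes — county
polygons with exact county-by-cell overlap areas, a county-level statistical
panel, per-year vigor rasters (NPP, NDVI) plus a cultivated-land layer, and a
grain yield/price table — with known embedded structure (planted hot/cold
health clusters, temporal trends) so every downstream stage can be tested
against ground truth.

Geometry is rasterized: counties are unions of fine sub-cells, so all overlap
areas are exact integer sub-cell counts times the sub-cell area and the
conservation law sum_i a_ij = A_j holds to the bit.  All randomness flows from
one root seed through independent named substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import (
    CropSpec,
    IndicatorSpec,
    PipelineConfig,
    TruthConfig,
    substream,
)
from .errors import ConfigurationError
from .grid import M2_PER_HM2, CountyLayout, OverlapMatrix, StudyGrid

# ---------------------------------------------------------------------------
# correlated random fields
# ---------------------------------------------------------------------------


def correlated_field(
    shape: tuple[int, int], correlation_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian random field with controllable autocorrelation.

    White noise smoothed with a Gaussian kernel of the given radius (in
    pixels) and re-standardized; range 0 returns the white field unchanged.
    """
    z = rng.standard_normal(shape)
    if correlation_range > 0:
        z = gaussian_filter(z, sigma=correlation_range, mode="reflect")
        if z.std() > 0:
            z = (z - z.mean()) / z.std()
    return z


def cluster_bumps(shape: tuple[int, int], truth: TruthConfig, scale: float = 1.0) -> np.ndarray:
    """Deterministic sum of the planted Gaussian anomalies (z units).

    ``scale`` converts cell units to pixel units when the target raster is
    finer than the evaluation grid.
    """
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    out = np.zeros(shape)
    for c in truth.clusters:
        d2 = (rows - c.row * scale) ** 2 + (cols - c.col * scale) ** 2
        out += c.amplitude * np.exp(-d2 / (2.0 * (c.radius * scale) ** 2))
    return out


# ---------------------------------------------------------------------------
# region geometry
# ---------------------------------------------------------------------------


def generate_study_region(
    n_rows: int,
    n_cols: int,
    cell_size_m: float,
    n_counties: int,
    seed: int,
    *,
    fine_factor: int = 10,
    years: list[int] | tuple[int, ...] = (0,),
    truth: TruthConfig | None = None,
) -> tuple[StudyGrid, CountyLayout, dict[str, OverlapMatrix]]:
    """Build the evaluation grid, a contiguous county partition, and both
    overlap-matrix variants.

    Counties are Voronoi patches of fine sub-cells around random seed points,
    so they partition the rectangle exactly.  The cultivated variant assumes a
    uniform cultivated fraction within each evaluation cell (the fraction
    itself varies smoothly in space), which keeps both conservation laws
    exact.
    """
    if n_rows < 1 or n_cols < 1 or cell_size_m <= 0 or fine_factor < 1:
        raise ConfigurationError("invalid grid dimensions")
    if n_counties < 1 or n_rows * n_cols < n_counties:
        raise ConfigurationError("invalid county count")
    truth = truth or TruthConfig()

    f = fine_factor
    fr, fc = n_rows * f, n_cols * f
    rng = substream(seed, "region")

    # Voronoi assignment of fine sub-cells to county seed points.
    seed_idx = rng.choice(fr * fc, size=n_counties, replace=False)
    seed_rc = np.column_stack(np.divmod(seed_idx, fc)).astype(float)
    rr, cc = np.meshgrid(np.arange(fr), np.arange(fc), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d2 = ((pts[:, None, :] - seed_rc[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1).reshape(fr, fc).astype(np.int64)
    # ties resolved by argmin's first-index rule -> deterministic
    layout = CountyLayout(n_counties=n_counties, fine_factor=f, fine_assignment=assignment)

    # Smooth cultivated fraction per evaluation cell, mildly coupled to the
    # planted health clusters (healthier cells keep more cropland).
    rng_c = substream(seed, "cultivated")
    zfield = correlated_field((n_rows, n_cols), truth.correlation_range, rng_c)
    zfield = zfield + 0.5 * cluster_bumps((n_rows, n_cols), truth)
    frac = np.clip(truth.cultivated_mean + truth.cultivated_sd * zfield, 0.05, 0.95)

    cell_area = cell_size_m**2 / M2_PER_HM2
    cult = pd.DataFrame(
        [
            (cid, int(y), frac.ravel()[cid] * cell_area)
            for y in years
            for cid in range(n_rows * n_cols)
        ],
        columns=["cell_id", "year", "cultivated_area_hm2"],
    )
    grid = StudyGrid(n_rows=n_rows, n_cols=n_cols, cell_size_m=cell_size_m, cultivated_area=cult)

    # Exact overlaps: count fine sub-cells per (cell, county).
    sub_area = (cell_size_m / f) ** 2 / M2_PER_HM2
    cell_of_fine = (rr // f) * n_cols + (cc // f)
    pairs = pd.DataFrame(
        {"cell_id": cell_of_fine.ravel(), "county_id": assignment.ravel()}
    )
    counts = pairs.value_counts(["county_id", "cell_id"]).rename("n").reset_index()
    counts = counts.sort_values(["county_id", "cell_id"]).reset_index(drop=True)
    total = counts.assign(area_hm2=counts["n"] * sub_area).drop(columns="n")
    ov_total = OverlapMatrix(entries=total, variant="total", n_cells=grid.n_cells)

    cult_entries = total.copy()
    cult_entries["area_hm2"] = cult_entries["area_hm2"] * frac.ravel()[
        cult_entries["cell_id"].to_numpy()
    ]
    ov_cult = OverlapMatrix(entries=cult_entries, variant="cultivated", n_cells=grid.n_cells)
    return grid, layout, {"total": ov_total, "cultivated": ov_cult}


# ---------------------------------------------------------------------------
# county panel
# ---------------------------------------------------------------------------


def generate_county_panel(
    layout: CountyLayout,
    years: list[int],
    indicator_specs: list[IndicatorSpec],
    seed: int,
) -> pd.DataFrame:
    """Long county panel (county_id, year, indicator, value).

    value = (mean + trend * (year - year0)) * county_factor + noise, clipped
    to the indicator's semantic range.  The multiplicative county factor is
    log-normal-ish (1 + N(0, county_sd), floored at 0.1) and constant in time,
    so counties keep a stable ordering unless noise dominates.
    """
    year0 = min(years)
    frames = []
    for spec in indicator_specs:
        rng = substream(seed, f"panel:{spec.code}")
        factor = np.maximum(1.0 + spec.county_sd * rng.standard_normal(layout.n_counties), 0.1)
        for year in years:
            base = (spec.mean + spec.trend * (year - year0)) * factor
            vals = base + spec.noise * rng.standard_normal(layout.n_counties)
            if spec.kind == "percent":
                vals = np.clip(vals, 0.0, 100.0)
            elif spec.kind == "nonneg":
                vals = np.clip(vals, 0.0, None)
            frames.append(
                pd.DataFrame(
                    {
                        "county_id": layout.county_ids,
                        "year": year,
                        "indicator": spec.code,
                        "value": vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def generate_rasters(
    grid: StudyGrid,
    truth: TruthConfig,
    years: list[int],
    seed: int,
    *,
    supersample: int = 5,
) -> dict[str, dict[int, np.ndarray]]:
    """Per-year NPP and NDVI rasters at ``supersample`` pixels per cell side.

    Both variables share the planted cluster anomalies (plus independent
    correlated noise), so cells inside a positive cluster have elevated
    NPP/NDVI in every year — the known hot spots for the spatial statistics.
    """
    s = supersample
    shape = (grid.n_rows * s, grid.n_cols * s)
    bumps = cluster_bumps(shape, truth, scale=float(s))
    year0 = min(years)
    out: dict[str, dict[int, np.ndarray]] = {"npp": {}, "ndvi": {}}
    for var, mean, sd, trend, lo, hi in (
        ("npp", truth.npp_mean, truth.npp_sd, truth.npp_trend, 0.0, np.inf),
        ("ndvi", truth.ndvi_mean, truth.ndvi_sd, truth.ndvi_trend, 0.0, 1.0),
    ):
        rng = substream(seed, f"raster:{var}")
        for year in years:
            z = correlated_field(shape, truth.correlation_range * s, rng) + bumps
            vals = mean + trend * (year - year0) + sd * z
            out[var][year] = np.clip(vals, lo, hi)
    return out


# ---------------------------------------------------------------------------
# whole scenario
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """All pipeline inputs of one synthetic study, in memory."""

    config: PipelineConfig
    seed: int
    grid: StudyGrid
    layout: CountyLayout
    overlaps: dict[str, OverlapMatrix]
    panel: pd.DataFrame
    rasters: dict[str, dict[int, np.ndarray]]
    crops: pd.DataFrame = field(repr=False)


def _crop_table(crops: list[CropSpec], total_grain_area_hm2: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "crop": [c.name for c in crops],
            "area_hm2": [c.area_share * total_grain_area_hm2 for c in crops],
            "yield_kg_per_hm2": [c.yield_kg_per_hm2 for c in crops],
            "price_yuan_per_kg": [c.price_yuan_per_kg for c in crops],
        }
    )


def generate_scenario(config: PipelineConfig, seed: int | None = None) -> Scenario:
    """Generate every pipeline input for one seeded scenario (in memory)."""
    seed = config.seed if seed is None else seed
    g = config.grid
    grid, layout, overlaps = generate_study_region(
        g.n_rows,
        g.n_cols,
        g.cell_size_m,
        g.n_counties,
        seed,
        fine_factor=g.fine_factor,
        years=config.years,
        truth=config.truth,
    )
    panel = generate_county_panel(layout, config.years, config.indicators, seed)
    rasters = generate_rasters(grid, config.truth, config.years, seed, supersample=g.supersample)
    total_cult = grid.cultivated_vector(config.years[0]).sum()
    crops = _crop_table(config.crops, total_cult)
    return Scenario(
        config=config,
        seed=seed,
        grid=grid,
        layout=layout,
        overlaps=overlaps,
        panel=panel,
        rasters=rasters,
        crops=crops,
    )


def _county_geojson(layout: CountyLayout, cell_size_m: float, n_rows: int) -> dict:
    """County polygons as GeoJSON, built from row-run rectangles."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    f = layout.fine_factor
    sub = cell_size_m / f
    fr, fc = layout.fine_assignment.shape
    height_m = n_rows * cell_size_m
    features = []
    for county in layout.county_ids:
        rects = []
        for r in range(fr):
            row = layout.fine_assignment[r] == county
            if not row.any():
                continue
            # merge horizontal runs into strips
            edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
            for c0, c1 in zip(edges[::2], edges[1::2]):
                y_top = height_m - r * sub
                rects.append(box(c0 * sub, y_top - sub, c1 * sub, y_top))
        geom = unary_union(rects)
        features.append(
            {
                "type": "Feature",
                "properties": {"county_id": int(county)},
                "geometry": mapping(geom),
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_scenario(scenario: Scenario, out_dir: str | Path) -> Path:
    """Write a scenario directory readable by the pipeline I/O layer.

    Layout: grid.json, overlaps_{total,cultivated}.csv, panel.csv,
    cultivated_area.csv, crops.csv, rasters/{npp,ndvi}_<year>.csv (plain grid
    dumps), counties.geojson (optional), truth.json sidecar.
    """
    out = Path(out_dir)
    try:
        (out / "rasters").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create scenario directory {out}: {exc}") from exc

    g = scenario.grid
    meta = {
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "cell_size_m": g.cell_size_m,
        "supersample": scenario.config.grid.supersample,
        "years": list(scenario.config.years),
        "n_counties": scenario.layout.n_counties,
    }
    (out / "grid.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    from .pipeline_io import write_table  # late import to avoid a cycle

    for variant, ov in scenario.overlaps.items():
        write_table(ov.entries, out / f"overlaps_{variant}.csv")
    write_table(scenario.panel, out / "panel.csv")
    write_table(g.cultivated_area, out / "cultivated_area.csv")
    write_table(scenario.crops, out / "crops.csv")
    for var, layers in scenario.rasters.items():
        for year, arr in layers.items():
            np.savetxt(out / "rasters" / f"{var}_{year}.csv", arr, delimiter=",", fmt="%.17g")

    if scenario.config.write_geojson:
        gj = _county_geojson(scenario.layout, g.cell_size_m, g.n_rows)
        (out / "counties.geojson").write_text(json.dumps(gj, sort_keys=True))

    truth = {
        "seed": scenario.seed,
        "correlation_range": scenario.config.truth.correlation_range,
        "clusters": [c.model_dump() for c in scenario.config.truth.clusters],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out


def generate_full_scenario(
    config: PipelineConfig, out_dir: str | Path, seed: int | None = None
) -> Scenario:
    """Generate a scenario and write it to ``out_dir``; returns the scenario."""
    scenario = generate_scenario(config, seed=seed)
    write_scenario(scenario, out_dir)
    return scenario
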