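"""I/O adapters and the end-to-end pipeline orchestrator.

CSV (long format) is the canonical interchange; numeric fields are written
with 17 significant digits so write-then-read round-trips to 1e-12 and
reruns are byte-identical.  Rasters travel as plain CSV grid dumps, county
polygons as GeoJSON, diagnostics/breaks/manifests as JSON with sorted keys.

``run_all`` executes the stages in method order — simulate, disaggregate,
indicators, weights, health, spatial, zoning — on a scenario directory,
logging row counts at stage boundaries and writing a manifest with seeds and
input digests.  Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import disaggregation, health, indicators, spatial, synthetic, weighting, zoning
from .config import PipelineConfig, substream
from .errors import CLSHError, StageError
from .grid import OverlapMatrix, StudyGrid

log = logging.getLogger("clsh")

FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# adapters
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise CLSHError(f"cannot parse table {path}: {exc}") from exc


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True))
    return path


def read_raster_csv(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except (ValueError, OSError) as exc:
        raise CLSHError(f"cannot parse raster {path}: {exc}") from exc
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise CLSHError(f"raster {path} has shape {arr.shape}, expected {expected_shape}")
    return arr


def read_scenario(scenario_dir: str | Path):
    """Load a scenario directory written by :func:`synthetic.write_scenario`."""
    d = Path(scenario_dir)
    meta = json.loads((d / "grid.json").read_text())
    cult = read_table(d / "cultivated_area.csv")
    grid = StudyGrid(
        n_rows=meta["n_rows"],
        n_cols=meta["n_cols"],
        cell_size_m=meta["cell_size_m"],
        cultivated_area=cult,
    )
    overlaps = {
        v: OverlapMatrix(
            entries=read_table(d / f"overlaps_{v}.csv"), variant=v, n_cells=grid.n_cells
        )
        for v in ("total", "cultivated")
    }
    panel = read_table(d / "panel.csv")
    s = meta["supersample"]
    shape = (meta["n_rows"] * s, meta["n_cols"] * s)
    rasters = {
        var: {
            int(y): read_raster_csv(d / "rasters" / f"{var}_{y}.csv", shape)
            for y in meta["years"]
        }
        for var in ("npp", "ndvi")
    }
    crops = read_table(d / "crops.csv")
    return meta, grid, overlaps, panel, rasters, crops


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except CLSHError as exc:
                raise StageError(name, exc) from exc
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, workdir: Path, seed: int):
    scen = synthetic.generate_full_scenario(config, workdir / "scenario", seed=seed)
    log.info("simulate: %d cells, %d counties, %d panel rows",
             scen.grid.n_cells, scen.layout.n_counties, len(scen.panel))
    return scen


@_stage("disaggregation")
def stage_disaggregate(config: PipelineConfig, workdir: Path) -> pd.DataFrame:
    _, grid, overlaps, panel, rasters, _ = read_scenario(workdir / "scenario")
    frames = []
    for spec in config.indicators:
        frames.append(
            disaggregation.area_weighted_index(
                panel, overlaps[spec.variant], spec.code, years=config.years
            )
        )
    for var, code in (("npp", "npp_mean"), ("ndvi", "D10")):
        for year in config.years:
            frames.append(
                disaggregation.zonal_mean(rasters[var][year], grid, year=year, indicator=code)
            )
    series = pd.concat(frames, ignore_index=True)
    write_table(series, workdir / "grid_series.csv")
    log.info("disaggregation: %d grid series rows", len(series))
    return series


@_stage("indicators")
def stage_indicators(config: PipelineConfig, workdir: Path) -> pd.DataFrame:
    _, grid, _, _, _, crops = read_scenario(workdir / "scenario")
    series = read_table(workdir / "grid_series.csv")
    cult = grid.cultivated_area.rename(columns={"cultivated_area_hm2": "value"})

    npp = series[series["indicator"] == "npp_mean"]
    merged = npp.merge(cult, on=["cell_id", "year"], suffixes=("_npp", "_area"))
    d9 = merged[["cell_id", "year"]].copy()
    d9["indicator"] = "D9"
    d9["value"] = indicators.cultivated_productivity(
        merged["value_npp"].to_numpy(), merged["value_area"].to_numpy()
    )

    d12 = cult[["cell_id", "year"]].copy()
    d12["indicator"] = "D12"
    d12["value"] = indicators.biological_abundance(
        cult["value"].to_numpy(), grid.cell_area_hm2
    )

    total_area = grid.cultivated_vector(config.years[0]).sum()
    ej = indicators.grain_economic_value(crops, total_area)
    esv_table = indicators.revise_esv_coefficients(ej)
    write_table(esv_table, workdir / "esv_table.csv")
    esv = indicators.esv_response_indicators(esv_table, grid.cultivated_area)

    panel_series = series[~series["indicator"].isin(["npp_mean"])]
    cube = indicators.assemble_indicator_cube([panel_series, d9, d12, esv])
    write_table(cube, workdir / "indicator_cube.csv")
    log.info("indicators: cube %d rows, Ej=%.3f yuan/hm2", len(cube), ej)
    return cube


@_stage("weighting")
def stage_weights(config: PipelineConfig, workdir: Path) -> weighting.WeightSet:
    cube = read_table(workdir / "indicator_cube.csv")
    normalized = weighting.minmax_normalize(cube)
    write_table(normalized.data, workdir / "normalized_cube.csv")
    ws = weighting.compute_weight_set(
        normalized,
        variance_target=config.weighting.variance_target,
        loading_threshold=config.weighting.loading_threshold,
        fixed_weights=config.weighting.fixed_weights,
    )
    write_table(ws.table(), workdir / "weights.csv")
    write_json(ws.diagnostics, workdir / "weight_diagnostics.json")
    log.info("weighting: %d indicators retained", len(ws.indicators))
    return ws


@_stage("health")
def stage_health(config: PipelineConfig, workdir: Path) -> pd.DataFrame:
    normalized_data = read_table(workdir / "normalized_cube.csv")
    wtab = read_table(workdir / "weights.csv").set_index("indicator")
    ws = weighting.WeightSet(
        indicators=list(wtab.index),
        pca=wtab["pca_weight"],
        critic=wtab["critic_weight"],
        comprehensive=wtab["comprehensive_weight"],
    )
    normalized = weighting.NormalizedCube(data=normalized_data, extrema=pd.DataFrame())
    surface = health.compute_clshi(normalized, ws)
    graded, brk = health.grade_surface(
        surface, k=config.classification.n_classes, pooled=config.classification.pooled
    )
    write_table(graded, workdir / "health_surface.csv")
    if isinstance(brk, dict):
        write_json({str(y): list(b.bounds) for y, b in brk.items()}, workdir / "breaks.json")
    else:
        write_json({"pooled": list(brk.bounds), "gvf": brk.gvf}, workdir / "breaks.json")
    write_table(health.timeseries_summary(graded), workdir / "timeseries_summary.csv")
    log.info("health: %d cell-years graded", len(graded))
    return graded


@_stage("spatial")
def stage_spatial(config: PipelineConfig, workdir: Path, seed: int) -> dict:
    _, grid, *_ = read_scenario(workdir / "scenario")
    surface = read_table(workdir / "health_surface.csv")
    sp = config.spatial
    w_moran = build_weights_for(grid, sp.moran_scheme, sp, for_gistar=False)
    w_gistar = build_weights_for(grid, "distance", sp, for_gistar=True)

    moran_out, lisa_frames, gi_frames = {}, [], []
    for year in config.years:
        vals = (
            surface[surface["year"] == year]
            .sort_values("cell_id")["clshi"]
            .to_numpy()
        )
        res = spatial.global_morans_i(
            vals, w_moran, sp.n_permutations, seed=substream(seed, f"moran:{year}").integers(2**31)
        )
        moran_out[str(year)] = {
            "I": res.i,
            "expected": res.expected,
            "p_sim": res.p_sim,
            "z_sim": res.z_sim,
        }
        lisa = spatial.local_moran_lisa(
            vals, w_moran, sp.n_permutations, sp.alpha,
            seed=substream(seed, f"lisa:{year}").integers(2**31),
        )
        lisa.insert(0, "year", year)
        lisa_frames.append(lisa)
        gi = spatial.getis_ord_gistar(vals, w_gistar)
        gi.insert(0, "year", year)
        gi_frames.append(gi)

    write_json(moran_out, workdir / "moran.json")
    write_table(pd.concat(lisa_frames, ignore_index=True), workdir / "lisa.csv")
    write_table(pd.concat(gi_frames, ignore_index=True), workdir / "gistar.csv")
    log.info("spatial: %d years analyzed", len(config.years))
    return moran_out


def build_weights_for(grid, scheme, sp_config, for_gistar: bool):
    if for_gistar:
        return spatial.build_weights(
            grid,
            "distance",
            distance_band_m=sp_config.gistar_distance_factor * grid.cell_size_m,
            include_self=True,
            row_standardize=False,
        )
    if scheme == "distance":
        return spatial.build_weights(
            grid,
            "distance",
            distance_band_m=sp_config.gistar_distance_factor * grid.cell_size_m,
            row_standardize=True,
        )
    return spatial.build_weights(grid, scheme, row_standardize=True)


@_stage("zoning")
def stage_zoning(config: PipelineConfig, workdir: Path) -> pd.DataFrame:
    _, grid, *_ = read_scenario(workdir / "scenario")
    surface = read_table(workdir / "health_surface.csv")
    y0, y1 = config.years[0], config.years[-1]

    tables = []
    for year in config.years:
        sub = surface[surface["year"] == year].sort_values("cell_id")
        tables.append(
            zoning.grade_area_table(
                sub["grade"].to_numpy(), grid.cultivated_vector(year), year=year
            )
        )
    areas = pd.concat(tables, ignore_index=True)
    write_table(areas, workdir / "grade_areas.csv")

    changes = []
    year_pairs = list(zip(config.years[:-1], config.years[1:]))
    if (y0, y1) not in year_pairs and y0 != y1:
        year_pairs.append((y0, y1))
    for a, b in year_pairs:
        cs = zoning.change_statistics(
            areas[areas["year"] == a], areas[areas["year"] == b]
        )
        cs.insert(0, "period", f"{a}-{b}")
        changes.append(cs)
    write_table(pd.concat(changes, ignore_index=True), workdir / "change_statistics.csv")

    g_start = surface[surface["year"] == y0].sort_values("cell_id")["grade"].to_numpy()
    g_end = surface[surface["year"] == y1].sort_values("cell_id")["grade"].to_numpy()
    tzm = zoning.transition_zone_map(g_start, g_end)
    write_table(tzm, workdir / "transition_zones.csv")
    zs = zoning.zone_statistics(tzm, grid.cultivated_vector(y1))
    write_table(zs, workdir / "zone_statistics.csv")
    log.info("zoning: %d cells zoned", len(tzm))
    return tzm


STAGE_OUTPUTS = [
    "scenario/panel.csv",
    "grid_series.csv",
    "indicator_cube.csv",
    "weights.csv",
    "health_surface.csv",
    "moran.json",
    "zone_statistics.csv",
]


def run_all(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run every stage in order on a fresh scenario; returns the result dir.

    Deterministic given (config, seed): rerunning writes byte-identical
    outputs.  The manifest records the seed, the config, and a SHA-256 digest
    of every stage output.
    """
    workdir = Path(out_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)

    stage_simulate(config, workdir, seed)
    stage_disaggregate(config, workdir)
    stage_indicators(config, workdir)
    stage_weights(config, workdir)
    stage_health(config, workdir)
    stage_spatial(config, workdir, seed)
    stage_zoning(config, workdir)

    manifest = {
        "seed": seed,
        "config": config.model_dump(),
        "stages": [
            {"output": rel, "sha256": _digest(workdir / rel)} for rel in STAGE_OUTPUTS
        ],
    }
    write_json(manifest, workdir / "manifest.json")
    return workdir
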