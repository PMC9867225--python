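"""County-to-grid disaggregation.

County statistics are mapped onto grid cells by area weighting: the value of
a cell is the overlap-area-weighted mean of the counties it intersects,

    Y_i = sum_j a_ij X_j / sum_j a_ij,

with the total-land overlap variant for population/economic densities and the
cultivated-land variant for per-cultivated-area intensities.  The
overlap-normalized denominator makes Y_i a convex combination of the county
values (a cell wholly inside one county inherits that county's value
exactly).  A ``strict_literal`` mode divides by the sum of full county areas
instead, reproducing the alternative normalization in which cells touching
large counties are deflated; it is provided for comparison only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataCompletenessError, UndefinedCellError
from .grid import OverlapMatrix, StudyGrid


def area_weighted_index(
    panel: pd.DataFrame,
    overlaps: OverlapMatrix,
    indicator: str,
    *,
    years: list[int] | None = None,
    strict_literal: bool = False,
) -> pd.DataFrame:
    """Disaggregate one panel indicator to the grid.

    Parameters
    ----------
    panel
        Long table (county_id, year, indicator, value).
    overlaps
        Overlap matrix of the variant appropriate for the indicator.
    years
        Years to process; defaults to every year present for the indicator.

    Returns
    -------
    Long table (cell_id, year, indicator, value).
    """
    sub = panel[panel["indicator"] == indicator]
    if sub.empty:
        raise DataCompletenessError(f"indicator {indicator!r} absent from panel")
    years = sorted(sub["year"].unique()) if years is None else list(years)

    counties = overlaps.entries["county_id"].unique()
    n_counties = int(counties.max()) + 1
    a = overlaps.to_dense(n_counties)  # (n_cells, n_counties)
    denom = a.sum(axis=1)
    zero = np.flatnonzero(denom <= 0)
    if zero.size:
        raise UndefinedCellError(
            f"cells with zero {overlaps.variant} overlap: {zero.tolist()[:20]}", zero
        )
    if strict_literal:
        denom = np.full_like(denom, overlaps.county_totals().sum())

    wide = sub.pivot(index="county_id", columns="year", values="value")
    frames = []
    for year in years:
        if year not in wide.columns:
            raise DataCompletenessError(f"no {indicator!r} values for year {year}")
        x = wide[year].reindex(np.arange(n_counties))
        needed = x.iloc[counties]
        if needed.isna().any():
            missing = needed[needed.isna()].index.tolist()
            raise DataCompletenessError(
                f"{indicator!r} year {year}: missing counties {missing}"
            )
        y = a @ x.fillna(0.0).to_numpy() / denom
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(overlaps.n_cells),
                    "year": year,
                    "indicator": indicator,
                    "value": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def zonal_mean(
    raster: np.ndarray,
    grid: StudyGrid,
    *,
    year: int | None = None,
    indicator: str = "raster",
) -> pd.DataFrame:
    """Arithmetic mean of raster pixels per grid cell.

    The raster must tile the grid with an integer number of pixels per cell
    side (pixel centers then fall unambiguously in exactly one cell).
    """
    r, c = raster.shape
    if r % grid.n_rows or c % grid.n_cols or (r // grid.n_rows) != (c // grid.n_cols):
        raise ConfigurationError(
            f"raster {raster.shape} does not tile the {grid.n_rows}x{grid.n_cols} grid"
        )
    s = r // grid.n_rows
    if s == 0:
        raise UndefinedCellError("raster coarser than the grid: cells without pixels")
    means = raster.reshape(grid.n_rows, s, grid.n_cols, s).mean(axis=(1, 3))
    out = pd.DataFrame(
        {
            "cell_id": grid.cell_ids,
            "year": -1 if year is None else year,
            "indicator": indicator,
            "value": means.ravel(),
        }
    )
    if year is None:
        out = out.drop(columns="year")
    return out
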