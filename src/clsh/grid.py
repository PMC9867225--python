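"""Core lattice containers: the evaluation grid, the county partition, and the
county-by-cell overlap matrix.

Conventions (used everywhere in the package):

* planar coordinates, x east / y north, in metres;
* cell ids are 0-based, dense, row-major from the north-west corner;
* areas are in hectares (hm^2); a 5 km x 5 km cell is 2500 hm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

M2_PER_HM2 = 1.0e4


@dataclass(frozen=True)
class StudyGrid:
    """Regular square evaluation lattice.

    ``cultivated_area`` is a long table (cell_id, year, cultivated_area_hm2);
    the cultivated extent of a cell never exceeds the cell area.
    """

    n_rows: int
    n_cols: int
    cell_size_m: float
    cultivated_area: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size_m <= 0:
            raise ConfigurationError(
                f"invalid grid dimensions {self.n_rows}x{self.n_cols} @ {self.cell_size_m} m"
            )
        bad = self.cultivated_area["cultivated_area_hm2"]
        if ((bad < -1e-9) | (bad > self.cell_area_hm2 + 1e-9)).any():
            raise ConfigurationError("cultivated area outside [0, cell area]")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_hm2(self) -> float:
        return self.cell_size_m**2 / M2_PER_HM2

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centres; row 0 is the northern edge."""
        rows, cols = np.divmod(self.cell_ids, self.n_cols)
        x = (cols + 0.5) * self.cell_size_m
        y = (self.n_rows - rows - 0.5) * self.cell_size_m
        return np.column_stack([x, y])

    def row_col(self, cell_id: np.ndarray | int):
        return np.divmod(cell_id, self.n_cols)

    def cultivated_vector(self, year: int) -> np.ndarray:
        sub = self.cultivated_area[self.cultivated_area["year"] == year]
        if len(sub) != self.n_cells:
            raise ConfigurationError(f"no complete cultivated-area layer for {year}")
        return (
            sub.set_index("cell_id")["cultivated_area_hm2"]
            .reindex(self.cell_ids)
            .to_numpy()
        )


@dataclass(frozen=True)
class CountyLayout:
    """Partition of the study rectangle into counties.

    ``fine_assignment`` maps each fine sub-cell (fine_factor x finer than the
    evaluation grid, row-major) to exactly one 0-based county id.
    """

    n_counties: int
    fine_factor: int
    fine_assignment: np.ndarray = field(repr=False)  # (n_rows*f, n_cols*f) int

    def __post_init__(self):
        present = np.unique(self.fine_assignment)
        if not np.array_equal(present, np.arange(self.n_counties)):
            raise ConfigurationError("counties must partition the region with dense ids")

    @property
    def county_ids(self) -> np.ndarray:
        return np.arange(self.n_counties)


@dataclass(frozen=True)
class OverlapMatrix:
    """Sparse county x cell intersection areas a_ij (hm^2).

    ``variant`` is ``"total"`` (full land) or ``"cultivated"``.  County totals
    A_j are the column sums by construction: sum_i a_ij == A_j exactly.
    """

    entries: pd.DataFrame  # columns: county_id, cell_id, area_hm2
    variant: str
    n_cells: int

    def __post_init__(self):
        if self.variant not in ("total", "cultivated"):
            raise ConfigurationError(f"unknown overlap variant {self.variant!r}")
        if (self.entries["area_hm2"] < 0).any():
            raise ConfigurationError("negative overlap area")

    def county_totals(self) -> pd.Series:
        """A_j per county (hm^2)."""
        return self.entries.groupby("county_id")["area_hm2"].sum()

    def cell_totals(self) -> pd.Series:
        """sum_j a_ij per cell, indexed over all cells (0 where no overlap)."""
        s = self.entries.groupby("cell_id")["area_hm2"].sum()
        return s.reindex(np.arange(self.n_cells), fill_value=0.0)

    def to_dense(self, n_counties: int) -> np.ndarray:
        """(n_cells, n_counties) dense a_ij matrix."""
        m = np.zeros((self.n_cells, n_counties))
        m[self.entries["cell_id"].to_numpy(), self.entries["county_id"].to_numpy()] = (
            self.entries["area_hm2"].to_numpy()
        )
        return m
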