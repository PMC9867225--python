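"""Inter-period change analysis and regulation zoning.

Grades are numeric 1 (I, best) to 5 (V, worst).  The change between two
endpoint years is summarized three ways:

* per-class cultivated area and share per year;
* per-class variation (hm^2) and change rate (%) between periods;
* a per-cell two-digit transition code (first digit the start grade, second
  the end grade) mapped to one of five regulation zones by the level
  difference delta = start - end:

  delta >= 2  moderate optimization   (improved by two or more grades)
  delta == 1  collaborative optimization
  delta == 0  potential promotion     (stable)
  delta == -1 key promotion           (dropped one grade)
  delta <= -2 priority promotion      (dropped two or more grades)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractError

GRADES = (1, 2, 3, 4, 5)

ZONES = (
    "moderate optimization",
    "collaborative optimization",
    "potential promotion",
    "key promotion",
    "priority promotion",
)


def grade_difference(grades_t1, grades_t2) -> np.ndarray:
    """Per-cell level difference start - end; positive = improvement.

    A cell moving from V (5) to III (3) scores +2.  Range -4 .. +4.
    """
    g1 = np.asarray(grades_t1, dtype=np.int64)
    g2 = np.asarray(grades_t2, dtype=np.int64)
    if g1.shape != g2.shape:
        raise ContractError("grade vectors cover different cell sets")
    for g in (g1, g2):
        if ((g < 1) | (g > 5)).any():
            raise ContractError("grades must be integers 1..5")
    return g1 - g2


def grade_area_table(grades, cultivated_area_hm2, year: int | None = None) -> pd.DataFrame:
    """Cultivated area and percentage share per grade class.

    Classes absent from the sample appear with zero area so period-to-period
    comparisons always align.
    """
    g = np.asarray(grades, dtype=np.int64)
    a = np.asarray(cultivated_area_hm2, dtype=float)
    if g.shape != a.shape:
        raise ContractError("grades and areas misaligned")
    area = pd.Series(a).groupby(g).sum().reindex(GRADES, fill_value=0.0)
    total = area.sum()
    out = pd.DataFrame(
        {
            "grade": list(GRADES),
            "area_hm2": area.to_numpy(),
            "proportion_pct": area.to_numpy() / total * 100.0 if total > 0 else 0.0,
        }
    )
    if year is not None:
        out.insert(0, "year", year)
    return out


def change_statistics(table_t1: pd.DataFrame, table_t2: pd.DataFrame) -> pd.DataFrame:
    """Per-class variation (hm^2) and change rate (%) between two periods.

    rate = (area_t2 - area_t1) / area_t1 * 100; a class with zero base area
    and nonzero variation gets a NaN rate (undefined marker).
    """
    a1 = table_t1.set_index("grade")["area_hm2"]
    a2 = table_t2.set_index("grade")["area_hm2"]
    if set(a1.index) != set(a2.index):
        raise ContractError("period tables cover different classes")
    a2 = a2.reindex(a1.index)
    variation = a2 - a1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(
            a1.to_numpy() > 0,
            variation.to_numpy() / a1.to_numpy() * 100.0,
            np.where(variation.to_numpy() == 0, 0.0, np.nan),
        )
    return pd.DataFrame(
        {"grade": a1.index, "variation_hm2": variation.to_numpy(), "change_rate_pct": rate}
    )


def transition_code(grade_start, grade_end) -> np.ndarray:
    """Two-digit transition code: 10 x start grade + end grade."""
    g1 = np.asarray(grade_start, dtype=np.int64)
    g2 = np.asarray(grade_end, dtype=np.int64)
    if ((g1 < 1) | (g1 > 5) | (g2 < 1) | (g2 > 5)).any():
        raise ContractError("grades must be integers 1..5")
    return 10 * g1 + g2


def zone_assignment(code) -> np.ndarray:
    """Regulation zone from the transition code's level difference.

    Total over all 25 codes; the two transitions unobserved in practice
    (15, 51) follow the same difference rule.
    """
    c = np.asarray(code, dtype=np.int64)
    start, end = c // 10, c % 10
    if ((start < 1) | (start > 5) | (end < 1) | (end > 5)).any():
        raise ContractError(f"invalid transition codes present")
    delta = start - end
    idx = np.select(
        [delta >= 2, delta == 1, delta == 0, delta == -1],
        [0, 1, 2, 3],
        default=4,
    )
    return np.asarray(ZONES)[idx]


def transition_zone_map(
    grades_start, grades_end, cell_ids=None
) -> pd.DataFrame:
    """Per-cell transition codes and regulation zones for two endpoint years."""
    g1 = np.asarray(grades_start, dtype=np.int64)
    g2 = np.asarray(grades_end, dtype=np.int64)
    if g1.shape != g2.shape:
        raise ContractError("grade vectors cover different cell sets")
    code = transition_code(g1, g2)
    return pd.DataFrame(
        {
            "cell_id": np.arange(g1.size) if cell_ids is None else np.asarray(cell_ids),
            "grade_start": g1,
            "grade_end": g2,
            "code": code,
            "level_difference": g1 - g2,
            "zone": zone_assignment(code),
        }
    )


def zone_statistics(zone_map: pd.DataFrame, cultivated_area_hm2) -> pd.DataFrame:
    """Cultivated area and percentage share per regulation zone."""
    a = np.asarray(cultivated_area_hm2, dtype=float)
    if a.shape[0] != len(zone_map):
        raise ContractError("zone map and areas misaligned")
    area = pd.Series(a).groupby(zone_map["zone"].to_numpy()).sum()
    area = area.reindex(ZONES, fill_value=0.0)
    total = area.sum()
    return pd.DataFrame(
        {
            "zone": list(ZONES),
            "area_hm2": area.to_numpy(),
            "share_pct": area.to_numpy() / total * 100.0 if total > 0 else 0.0,
        }
    )


def round_half_up(x, decimals: int = 2):
    """Decimal rounding with ties away from zero, as statistical tables print."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
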