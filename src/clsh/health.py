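"""Composite health index, natural-breaks grading, and time-series summaries.

The cultivated-land system health index (CLSHI) of a cell-year is the
weighted sum of its normalized indicator values, CLSHI = sum_j z_j w_j, in
[0, 1] with higher = healthier.  Pressure/state/response sub-indices use the
same weights renormalized within each layer, so each sub-index also spans
[0, 1].  Because pressure indicators are cost-direction, a HIGH pressure
sub-index means LITTLE pressure; the complement is reported as
``raw_pressure`` for the opposite reading.

Grading uses exact Fisher-Jenks natural breaks (the dynamic program that
minimizes the within-class sum of squared deviations) with five classes,
fitted on the pooled cell-year sample so grades are comparable across years:
grade I is the highest-index class, grade V the lowest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClassificationError, ContractError
from .indicators import REGISTRY
from .weighting import NormalizedCube, WeightSet

GRADE_LABELS = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}
LAYERS = ("pressure", "state", "response")


# ---------------------------------------------------------------------------
# composite index
# ---------------------------------------------------------------------------


def compute_clshi(normalized: NormalizedCube, weights: WeightSet) -> pd.DataFrame:
    """Health surface: CLSHI and layer sub-indices per cell-year.

    Columns: cell_id, year, clshi, pressure_index, state_index,
    response_index, raw_pressure.
    """
    w = weights.comprehensive
    matrix = normalized.matrix()
    missing = set(w.index) - set(matrix.columns)
    if missing:
        raise ContractError(f"weights reference indicators absent from cube: {sorted(missing)}")
    matrix = matrix[list(w.index)]
    out = pd.DataFrame(index=matrix.index)
    out["clshi"] = matrix.to_numpy() @ w.to_numpy()
    for layer in LAYERS:
        cols = [c for c in w.index if REGISTRY[c].layer == layer]
        if not cols:
            out[f"{layer}_index"] = np.nan
            continue
        lw = w[cols] / w[cols].sum()
        out[f"{layer}_index"] = matrix[cols].to_numpy() @ lw.to_numpy()
    out["raw_pressure"] = 1.0 - out["pressure_index"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# Fisher-Jenks natural breaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JenksBreaks:
    """Optimal k-class partition of a 1-D sample.

    ``bounds`` has k+1 entries: data min, the k-1 interior class maxima, and
    the data max.  ``gvf`` is the goodness-of-variance fit
    1 - SSD_within / SSD_total.
    """

    k: int
    bounds: tuple[float, ...]
    within_ssd: float
    gvf: float

    @property
    def interior(self) -> np.ndarray:
        return np.asarray(self.bounds[1:-1])


def jenks_breaks(values, k: int = 5) -> JenksBreaks:
    """Exact Fisher-Jenks optimal classification.

    Dynamic program over the sorted sample: cost(j, i) is the SSD of the
    slice [j, i], computed from prefix sums; dp[c, i] is the minimal total
    SSD of splitting the first i+1 values into c classes.  O(k n^2) with a
    vectorized inner minimization; deterministic (ties broken by the earliest
    split).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if np.unique(x).size < k:
        raise ClassificationError(f"need >= {k} distinct values, got {np.unique(x).size}")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(j: np.ndarray, i: int) -> np.ndarray:
        # SSD of x[j..i] inclusive, vectorized over j
        cnt = i + 1 - j
        s = s1[i + 1] - s1[j]
        return (s2[i + 1] - s2[j]) - s * s / cnt

    dp = np.full((k + 1, n), np.inf)
    split = np.zeros((k + 1, n), dtype=np.int64)
    dp[1] = (s2[1:] - s1[1:] ** 2 / np.arange(1, n + 1))  # cost of x[0..i]
    for c in range(2, k + 1):
        for i in range(c - 1, n):
            j = np.arange(c - 1, i + 1)  # first index of the last class
            cand = dp[c - 1][j - 1] + seg_cost(j, i)
            best = int(np.argmin(cand))
            dp[c, i] = cand[best]
            split[c, i] = j[best]
    # backtrack class boundaries
    bounds = [float(x[-1])]
    i = n - 1
    for c in range(k, 1, -1):
        j = split[c, i]
        bounds.append(float(x[j - 1]))  # maximum of the previous class
        i = j - 1
    bounds.append(float(x[0]))
    bounds = tuple(bounds[::-1])
    total = float(seg_cost(np.array([0]), n - 1)[0])
    within = float(dp[k, n - 1])
    gvf = 1.0 - within / total if total > 0 else 1.0
    return JenksBreaks(k=k, bounds=bounds, within_ssd=within, gvf=gvf)


def grade(values, breaks: JenksBreaks) -> np.ndarray:
    """Assign 1..5 grades (I best) from the fitted breaks.

    Class intervals are right-closed: a value equal to an interior break
    belongs to the lower-index class.  Values outside the fitting range are
    clamped with a warning.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = breaks.bounds[0], breaks.bounds[-1]
    if ((x < lo) | (x > hi)).any():
        warnings.warn("values outside the break-fitting range were clamped", stacklevel=2)
        x = np.clip(x, lo, hi)
    cls = np.searchsorted(breaks.interior, x, side="left")  # 0 = lowest class
    return (breaks.k - cls).astype(np.int64)  # highest class -> grade 1 (I)


def grade_surface(
    surface: pd.DataFrame,
    k: int = 5,
    pooled: bool = True,
) -> tuple[pd.DataFrame, JenksBreaks | dict[int, JenksBreaks]]:
    """Attach Jenks grades to a health surface.

    Pooled mode (default) fits one break set on all cell-years so grades are
    comparable across years; per-year mode refits annually.
    """
    out = surface.copy()
    if pooled:
        brk = jenks_breaks(out["clshi"].to_numpy(), k)
        out["grade"] = grade(out["clshi"].to_numpy(), brk)
        out["grade_label"] = out["grade"].map(GRADE_LABELS)
        return out, brk
    breaks = {}
    out["grade"] = 0
    for year, sub in out.groupby("year"):
        brk = jenks_breaks(sub["clshi"].to_numpy(), k)
        breaks[int(year)] = brk
        out.loc[sub.index, "grade"] = grade(sub["clshi"].to_numpy(), brk)
    out["grade_label"] = out["grade"].map(GRADE_LABELS)
    return out, breaks


def timeseries_summary(surface: pd.DataFrame) -> pd.DataFrame:
    """Per-year max/min/mean of the composite index and each sub-index."""
    cols = ["clshi", "pressure_index", "state_index", "response_index"]
    agg = surface.groupby("year")[cols].agg(["max", "min", "mean"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()
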