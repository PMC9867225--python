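"""Lattice spatial statistics: global/local Moran's I and Getis-Ord Gi*.

Spatial weights are binary neighbor relations on the evaluation lattice —
rook or queen contiguity, or a fixed distance band (the only scheme that may
include the focal cell itself, as the starred Getis-Ord statistic requires).
Moran statistics row-standardize the weights; Gi* uses them binary.

Inference is permutation-based throughout: the global test randomly relabels
all values; the local (LISA) test uses conditional permutation, holding the
focal value fixed and drawing its neighbors from the remaining cells.  Both
pseudo-p values are two-sided on the absolute statistic,
p = (#{|stat_perm| >= |stat_obs|} + 1) / (n_perm + 1), which makes the
per-cell false-positive rate of the LISA labels approximately the nominal
alpha under exchangeability.  Gi* z-scores use the closed-form randomization
moments, and the hot/cold 5-level classes come from Fisher-Jenks on the
z-surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import cdist

from .config import substream
from .errors import ConfigurationError, UndefinedStatisticError
from .grid import StudyGrid
from .health import jenks_breaks

GISTAR_CLASS_LABELS = {1: "hot", 2: "sub-hot", 3: "neutral", 4: "sub-cold", 5: "cold"}


@dataclass(frozen=True)
class SpatialWeights:
    """Binary spatial weights with optional row standardization."""

    matrix: sparse.csr_matrix = field(repr=False)  # binary, n x n
    scheme: str
    row_standardized: bool
    includes_self: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def standardized(self) -> sparse.csr_matrix:
        """Row-standardized copy (rows with no neighbors stay zero)."""
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
        return sparse.diags(inv) @ self.matrix

    def working_matrix(self) -> sparse.csr_matrix:
        return self.standardized() if self.row_standardized else self.matrix.tocsr()

    def neighbor_lists(self) -> list[np.ndarray]:
        m = self.matrix.tocsr()
        return [m.indices[m.indptr[i]: m.indptr[i + 1]] for i in range(self.n)]


def build_weights(
    grid: StudyGrid,
    scheme: str = "queen",
    *,
    distance_band_m: float | None = None,
    include_self: bool = False,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Neighbor structure on the evaluation lattice.

    ``rook``/``queen`` are edge/edge-or-corner contiguity; ``distance``
    links cells whose centroid distance is <= ``distance_band_m``.  Only the
    distance scheme may include the focal cell (for Gi*).  Cells without any
    neighbor trigger an isolation warning.
    """
    n = grid.n_cells
    rows_idx, cols_idx = grid.row_col(grid.cell_ids)
    if scheme in ("rook", "queen"):
        if include_self:
            raise ConfigurationError("include_self is only meaningful for the distance scheme")
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        i_list, j_list = [], []
        for dr, dc in offsets:
            rr, cc2 = rows_idx + dr, cols_idx + dc
            ok = (rr >= 0) & (rr < grid.n_rows) & (cc2 >= 0) & (cc2 < grid.n_cols)
            i_list.append(grid.cell_ids[ok])
            j_list.append(rr[ok] * grid.n_cols + cc2[ok])
        i = np.concatenate(i_list)
        j = np.concatenate(j_list)
        w = sparse.csr_matrix((np.ones_like(i, dtype=float), (i, j)), shape=(n, n))
    elif scheme == "distance":
        if distance_band_m is None or distance_band_m <= 0:
            raise ConfigurationError("distance scheme needs a positive distance band")
        xy = grid.centroids()
        d = cdist(xy, xy)
        mask = d <= distance_band_m + 1e-9
        if not include_self:
            np.fill_diagonal(mask, False)
        w = sparse.csr_matrix(mask.astype(float))
    else:
        raise ConfigurationError(f"unknown weights scheme {scheme!r}")

    degrees = np.asarray(w.sum(axis=1)).ravel()
    isolated = np.flatnonzero(degrees - (1.0 if include_self else 0.0) <= 0)
    if isolated.size:
        warnings.warn(f"isolated cells under {scheme} scheme: {isolated.tolist()[:20]}",
                      stacklevel=2)
    return SpatialWeights(
        matrix=w, scheme=scheme, row_standardized=row_standardize, includes_self=include_self
    )


# ---------------------------------------------------------------------------
# global Moran's I
# ---------------------------------------------------------------------------


@dataclass
class MoranResult:
    i: float
    expected: float
    p_sim: float
    z_sim: float
    permuted_mean: float
    permuted_sd: float
    quadrant: np.ndarray = field(repr=False)  # per-cell "HH"/"LL"/"HL"/"LH"


def _moran_stat(z: np.ndarray, w: sparse.csr_matrix, s0: float) -> float:
    return float(z.size / s0 * (z @ (w @ z)) / (z @ z))


def global_morans_i(
    values,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with random-labeling permutation inference.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2;
    expectation -1/(n-1) under the null.  Scatter quadrants compare each
    cell's standardized value with its row-standardized spatial lag.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 or x.std() == 0:
        raise UndefinedStatisticError("Moran's I undefined: <2 cells or zero variance")
    w = weights.working_matrix()
    s0 = float(w.sum())
    z = x - x.mean()
    i_obs = _moran_stat(z, w, s0)

    rng = substream(seed, "moran")
    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        perms[k] = _moran_stat(rng.permutation(z), w, s0)
    p_sim = (np.count_nonzero(np.abs(perms) >= abs(i_obs)) + 1) / (n_permutations + 1)
    sd = perms.std(ddof=1)
    z_sim = (i_obs - perms.mean()) / sd if sd > 0 else np.inf

    zs = z / x.std()
    lag = weights.standardized() @ zs
    quadrant = np.where(
        zs >= 0,
        np.where(lag >= 0, "HH", "HL"),
        np.where(lag >= 0, "LH", "LL"),
    )
    return MoranResult(
        i=i_obs,
        expected=-1.0 / (n - 1),
        p_sim=float(p_sim),
        z_sim=float(z_sim),
        permuted_mean=float(perms.mean()),
        permuted_sd=float(sd),
        quadrant=quadrant,
    )


# ---------------------------------------------------------------------------
# local Moran (LISA)
# ---------------------------------------------------------------------------


def local_moran_lisa(
    values,
    weights: SpatialWeights,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Local Moran statistics with conditional-permutation labels.

    I_i = z_i * sum_j w_ij z_j on standardized deviations and
    row-standardized weights.  For each cell the neighbor values are redrawn
    from the other n-1 cells (same permutation pool across cells); cells with
    two-sided pseudo-p <= alpha are labeled by their scatter quadrant, the
    rest "ns".
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 or x.std() == 0:
        raise UndefinedStatisticError("local Moran undefined: <2 cells or zero variance")
    zs = (x - x.mean()) / x.std()
    wmat = weights.standardized()
    lag = wmat @ zs
    local_i = zs * lag

    nbrs = weights.neighbor_lists()
    max_k = max((len(a) for a in nbrs), default=0)
    rng = substream(seed, "lisa")
    # one (n_perm, max_k) block of permuted positions shared across cells
    rids = np.empty((n_permutations, max_k), dtype=np.int64)
    for p in range(n_permutations):
        rids[p] = rng.permutation(n - 1)[:max_k]

    p_sim = np.ones(n)
    idx_all = np.arange(n)
    for i in range(n):
        k = len(nbrs[i])
        if k == 0:
            continue
        others = np.delete(idx_all, i)
        draws = zs[others[rids[:, :k]]]  # (n_perm, k)
        lag_perm = draws.mean(axis=1) if weights.row_standardized else draws.sum(axis=1)
        perm_i = zs[i] * lag_perm
        p_sim[i] = (np.count_nonzero(np.abs(perm_i) >= abs(local_i[i])) + 1) / (
            n_permutations + 1
        )

    quadrant = np.where(
        zs >= 0, np.where(lag >= 0, "HH", "HL"), np.where(lag >= 0, "LH", "LL")
    )
    label = np.where(p_sim <= alpha, quadrant, "ns")
    return pd.DataFrame(
        {
            "cell_id": idx_all,
            "local_i": local_i,
            "p_sim": p_sim,
            "quadrant": quadrant,
            "label": label,
        }
    )


# ---------------------------------------------------------------------------
# Getis-Ord Gi*
# ---------------------------------------------------------------------------


def getis_ord_gistar(values, weights: SpatialWeights, n_classes: int = 5) -> pd.DataFrame:
    """Gi* concentration statistic with randomization z-scores.

    Gi* = sum_j w_ij x_j / sum_j x_j (ratio form, self included in the
    band); E[Gi*] = W_i / n and the z-score uses the standard Getis-Ord
    randomization variance.  The z-surface is cut into 5 hot->cold classes
    by Fisher-Jenks.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise UndefinedStatisticError("need >= 2 cells")
    s = np.sqrt((x**2).mean() - x.mean() ** 2)
    if s == 0:
        raise UndefinedStatisticError("Gi* undefined on a constant field")
    if not weights.includes_self:
        warnings.warn("Gi* conventionally includes the focal cell in its band", stacklevel=2)
    w = weights.matrix  # binary
    wi = np.asarray(w.sum(axis=1)).ravel()
    wx = w @ x
    total = x.sum()
    gistar = wx / total
    expected = wi / n
    num = wx - x.mean() * wi
    den = s * np.sqrt((n * wi - wi**2) / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.where(den > 0, num / den, np.nan)
    variance = (den / total) ** 2

    brk = jenks_breaks(zscore[np.isfinite(zscore)], n_classes)
    cls = np.searchsorted(brk.interior, zscore, side="left")
    klass = n_classes - cls  # top z interval -> class 1 = "hot"
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "gistar": gistar,
            "expected": expected,
            "variance": variance,
            "z": zscore,
            "klass": klass,
            "klass_label": pd.Series(klass).map(GISTAR_CLASS_LABELS).to_numpy(),
        }
    )
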