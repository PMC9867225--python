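"""Indicator normalization, screening diagnostics, and objective weighting.

Indicators are min-max scaled per indicator over the pooled cell-year sample,
direction-aware (cost indicators are reversed), so every normalized value
lies in [0, 1].  Two objective weighting routes are then combined:

* PCA weights — variance-proportion-weighted squared loadings over the
  principal components of the correlation matrix (components with eigenvalue
  >= 1), normalized to sum 1;
* CRITIC weights — contrast (standard deviation) times conflict
  (sum of 1 - r_jk against the other indicators), normalized.

The comprehensive weight is the renormalized average of the two.  KMO and
Bartlett sphericity diagnostics gate the PCA step, and a loading-based screen
reports which indicators carry enough common variance to retain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateIndicatorError,
    DiagnosticsError,
    ScreeningError,
    WeightingError,
)

# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizedCube:
    """Direction-aware min-max normalized cube plus the stored extrema."""

    data: pd.DataFrame = field(repr=False)  # cell_id, year, indicator, z
    extrema: pd.DataFrame = field(repr=False)  # indicator, min, max, direction

    def matrix(self, indicators: list[str] | None = None) -> pd.DataFrame:
        """(cell-year) x indicator wide matrix of normalized values."""
        wide = self.data.pivot(index=["cell_id", "year"], columns="indicator", values="z")
        return wide if indicators is None else wide[list(indicators)]


def minmax_normalize(cube: pd.DataFrame) -> NormalizedCube:
    """Normalize each indicator over all cells and years jointly.

    Benefit indicators: z = (x - min) / (max - min); cost indicators:
    z = (max - x) / (max - min).  A constant indicator has no usable
    contrast and raises :class:`DegenerateIndicatorError`.
    """
    g = cube.groupby("indicator")["value"]
    lo, hi = g.min(), g.max()
    flat = hi[hi - lo <= 0].index.tolist()
    if flat:
        raise DegenerateIndicatorError(f"constant indicators: {flat}")
    out = cube.copy()
    rng = (hi - lo).reindex(out["indicator"]).to_numpy()
    lo_v = lo.reindex(out["indicator"]).to_numpy()
    hi_v = hi.reindex(out["indicator"]).to_numpy()
    pos = out["direction"].to_numpy() > 0
    out["z"] = np.where(pos, (out["value"] - lo_v) / rng, (hi_v - out["value"]) / rng)
    extrema = pd.DataFrame(
        {
            "indicator": lo.index,
            "min": lo.to_numpy(),
            "max": hi.to_numpy(),
            "direction": [cube.loc[cube["indicator"] == c, "direction"].iloc[0] for c in lo.index],
        }
    )
    return NormalizedCube(
        data=out[["cell_id", "year", "indicator", "z", "layer"]]
        if "layer" in out
        else out[["cell_id", "year", "indicator", "z"]],
        extrema=extrema,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _correlation(matrix: np.ndarray) -> np.ndarray:
    sd = matrix.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise DiagnosticsError("zero-variance column in sample")
    return np.corrcoef(matrix, rowvar=False)


def kmo_bartlett(matrix: pd.DataFrame | np.ndarray) -> dict:
    """Kaiser-Meyer-Olkin sampling adequacy and Bartlett's sphericity test.

    KMO = sum r^2 / (sum r^2 + sum p^2) over off-diagonal pairs, where p are
    the partial correlations obtained from the inverse correlation matrix.
    Bartlett: chi2 = -(n - 1 - (2p + 5)/6) ln|R| on p(p-1)/2 degrees of
    freedom.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if p < 3:
        raise DiagnosticsError("need at least 3 indicators")
    if n <= p:
        raise DiagnosticsError("sample size must exceed indicator count")
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0 or logdet < -1e12:
        raise DiagnosticsError("singular correlation matrix; KMO undefined")
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise DiagnosticsError("singular correlation matrix; KMO undefined") from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    off = ~np.eye(p, dtype=bool)
    denom = (r[off] ** 2).sum() + (partial[off] ** 2).sum()
    kmo = (r[off] ** 2).sum() / denom if denom > 0 else float("nan")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return {
        "kmo": float(kmo),
        "bartlett_chi2": float(chi2),
        "bartlett_df": int(df),
        "bartlett_p": float(stats.chi2.sf(chi2, df)),
        "n_samples": int(n),
        "n_indicators": int(p),
    }


def _deduplicate_columns(matrix: pd.DataFrame, tol: float = 1e-12) -> list[str]:
    """One representative column per |r| = 1 correlation group (order kept)."""
    cols = list(matrix.columns)
    r = np.abs(np.corrcoef(matrix.to_numpy(dtype=float), rowvar=False))
    keep: list[str] = []
    for j, c in enumerate(cols):
        if not any(r[j, cols.index(k)] >= 1.0 - tol for k in keep):
            keep.append(c)
    return keep


# ---------------------------------------------------------------------------
# PCA screening and weights
# ---------------------------------------------------------------------------


def _pca(matrix: np.ndarray):
    """Eigen-decomposition of the correlation matrix, descending order.

    Returns (eigenvalues, loadings) with loadings[j, m] the loading of
    indicator j on component m (eigvec * sqrt(eigval)).
    """
    r = _correlation(matrix)
    vals, vecs = np.linalg.eigh(r)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    loadings = vecs[:, order] * np.sqrt(vals)
    return vals, loadings


def pca_screen(
    matrix: pd.DataFrame,
    variance_target: float = 0.80,
    loading_threshold: float = 0.5,
) -> dict:
    """Screen indicators by principal-component loadings.

    Components are retained until their cumulative explained variance reaches
    ``variance_target``; an indicator is retained iff its maximum absolute
    loading on a retained component reaches ``loading_threshold`` (low
    communality, not redundancy, is screened out).
    """
    cols = list(matrix.columns)
    x = matrix.to_numpy(dtype=float)
    vals, loadings = _pca(x)
    frac = vals / vals.sum()
    m = int(np.searchsorted(np.cumsum(frac), variance_target - 1e-12) + 1)
    m = min(m, len(vals))
    keep_mask = (np.abs(loadings[:, :m]) >= loading_threshold).any(axis=1)
    retained = [c for c, k in zip(cols, keep_mask) if k]
    if len(retained) < 2:
        raise ScreeningError(
            f"screening retained {len(retained)} indicator(s); lower the threshold"
        )
    return {
        "retained": retained,
        "dropped": [c for c, k in zip(cols, keep_mask) if not k],
        "n_components": m,
        "cumulative_variance": float(np.cumsum(frac)[m - 1]),
        "eigenvalues": vals.tolist(),
        "retained_fraction": retained_fraction(len(retained), len(cols)),
    }


def retained_fraction(n_retained: int, n_initial: int) -> float:
    """Share of indicators surviving screening, in percent."""
    if n_initial <= 0:
        raise WeightingError("initial indicator count must be positive")
    return 100.0 * n_retained / n_initial


def pca_weights(matrix: pd.DataFrame, retained: list[str] | None = None) -> pd.Series:
    """Objective weights from squared loadings on the Kaiser components.

    w_j  propto  sum_m loading_jm^2 x (lambda_m / sum_retained lambda), over
    components with eigenvalue >= 1 (always at least the first); normalized
    to sum 1.
    """
    cols = list(matrix.columns) if retained is None else list(retained)
    x = matrix[cols].to_numpy(dtype=float)
    vals, loadings = _pca(x)
    keep = vals >= 1.0 - 1e-9
    if not keep.any():
        keep[0] = True
    lam = vals[keep]
    load2 = loadings[:, keep] ** 2
    raw = load2 @ (lam / lam.sum())
    total = raw.sum()
    if total <= 0:
        raise WeightingError("degenerate PCA weight vector")
    return pd.Series(raw / total, index=cols, name="pca_weight")


def critic_weights(matrix: pd.DataFrame, retained: list[str] | None = None) -> pd.Series:
    """CRITIC weights: contrast intensity times conflict.

    C_j = sigma_j x sum_k (1 - r_jk); w_j = C_j / sum C.
    """
    cols = list(matrix.columns) if retained is None else list(retained)
    x = matrix[cols].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = [c for c, s in zip(cols, sd) if s <= 0]
        raise WeightingError(f"zero-variance indicators: {bad}")
    r = np.clip(np.corrcoef(x, rowvar=False), -1.0, 1.0)
    conflict = 1.0 - r
    conflict[conflict < 1e-12] = 0.0  # exact duplicates carry no information
    c = sd * conflict.sum(axis=1)
    total = c.sum()
    if total <= 0:
        raise WeightingError("all indicators perfectly correlated; CRITIC undefined")
    return pd.Series(c / total, index=cols, name="critic_weight")


def comprehensive_weights(pca_w: pd.Series, critic_w: pd.Series) -> pd.Series:
    """Average of the two objective weight vectors, renormalized to sum 1."""
    if len(pca_w) != len(critic_w) or set(pca_w.index) != set(critic_w.index):
        raise WeightingError("weight vectors cover different indicators")
    w = (pca_w + critic_w.reindex(pca_w.index)) / 2.0
    return (w / w.sum()).rename("comprehensive_weight")


# ---------------------------------------------------------------------------
# weight set
# ---------------------------------------------------------------------------


@dataclass
class WeightSet:
    """Screened indicator list with the three weight vectors and diagnostics."""

    indicators: list[str]
    pca: pd.Series = field(repr=False)
    critic: pd.Series = field(repr=False)
    comprehensive: pd.Series = field(repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicators,
                "pca_weight": self.pca.reindex(self.indicators).to_numpy(),
                "critic_weight": self.critic.reindex(self.indicators).to_numpy(),
                "comprehensive_weight": self.comprehensive.reindex(self.indicators).to_numpy(),
            }
        )


def compute_weight_set(
    normalized: NormalizedCube,
    variance_target: float = 0.80,
    loading_threshold: float = 0.5,
    fixed_weights: dict[str, float] | None = None,
) -> WeightSet:
    """Full weighting stage on a normalized cube.

    With ``fixed_weights`` the PCA/CRITIC machinery is bypassed and the given
    (indicator -> weight) map, renormalized, is used for all three vectors —
    the hook for reproducing published weight tables exactly.
    """
    if fixed_weights is not None:
        w = pd.Series(fixed_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise WeightingError("fixed weights must be nonnegative with positive sum")
        w = w / w.sum()
        return WeightSet(
            indicators=list(w.index),
            pca=w.rename("pca_weight"),
            critic=w.rename("critic_weight"),
            comprehensive=w.rename("comprehensive_weight"),
            diagnostics={"mode": "fixed"},
        )
    matrix = normalized.matrix()
    # Formula-derived indicators can be exact multiples of one another (the
    # four service values all scale cultivated area), which makes |R| = 0 and
    # KMO undefined on the full set.  Diagnostics then fall back to one
    # representative per perfectly-correlated group; screening and weighting
    # still run on the full set (PCA tolerates the singular correlation).
    try:
        diag = kmo_bartlett(matrix)
    except DiagnosticsError:
        rep = _deduplicate_columns(matrix)
        diag = kmo_bartlett(matrix[rep])
        diag["kmo_on"] = rep
    screen = pca_screen(matrix, variance_target, loading_threshold)
    retained = screen["retained"]
    pca_w = pca_weights(matrix, retained)
    critic_w = critic_weights(matrix, retained)
    comp = comprehensive_weights(pca_w, critic_w)
    diag.update({k: v for k, v in screen.items() if k != "retained"})
    return WeightSet(
        indicators=retained,
        pca=pca_w,
        critic=critic_w,
        comprehensive=comp,
        diagnostics=diag,
    )
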