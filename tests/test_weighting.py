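"""Normalization, factor-analysis diagnostics, and objective weights, each
checked against a textbook brute-force route."""

import numpy as np
import pandas as pd
import pytest

from clsh import weighting as wt
from clsh.errors import (
    DegenerateIndicatorError,
    DiagnosticsError,
    ScreeningError,
    WeightingError,
)
from conftest import make_cube

# mutually orthogonal zero-mean design vectors (n = 8)
F1 = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
F2 = np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)
G = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)


def frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestMinMaxNormalize:
    def _cube(self, values, direction):
        cube = make_cube(np.asarray(values)[:, None], ["D9"])
        cube["direction"] = direction
        return cube

    @pytest.mark.parametrize("direction,at_min,at_max", [(1, 0.0, 1.0), (-1, 1.0, 0.0)])
    def test_boundaries(self, direction, at_min, at_max):
        out = wt.minmax_normalize(self._cube([2.0, 4.0, 6.0], direction))
        z = out.data.sort_values("cell_id")["z"].to_numpy()
        assert z[0] == pytest.approx(at_min)
        assert z[-1] == pytest.approx(at_max)
        assert z[1] == pytest.approx(0.5)  # midpoint either direction

    def test_pooled_over_years(self):
        cube = make_cube(np.array([[0.0], [10.0], [5.0], [20.0]]), ["D9"],
                         years=(2000, 2005))
        out = wt.minmax_normalize(cube)
        # extrema taken over both years jointly
        assert out.extrema["min"].iloc[0] == 0.0
        assert out.extrema["max"].iloc[0] == 20.0
        assert out.data["z"].between(0, 1).all()

    def test_constant_indicator_rejected_by_name(self):
        with pytest.raises(DegenerateIndicatorError, match="D9"):
            wt.minmax_normalize(self._cube([3.0, 3.0, 3.0], 1))


class TestKMOBartlett:
    def test_exactly_independent_indicators(self):
        m = frame({"a": F1, "b": F2, "c": G})
        d = wt.kmo_bartlett(m)
        assert d["bartlett_chi2"] == pytest.approx(0.0, abs=1e-9)
        assert d["bartlett_p"] == pytest.approx(1.0)

    def test_duplicated_pair_is_singular(self):
        m = frame({"a": F1, "b": F1, "c": G})
        with pytest.raises(DiagnosticsError):
            wt.kmo_bartlett(m)

    def test_matches_textbook_brute_force(self, rng):
        n, p = 60, 5
        x = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
        d = wt.kmo_bartlett(frame({f"v{j}": x[:, j] for j in range(p)}))
        r = np.corrcoef(x, rowvar=False)
        # partial correlations via residual regression (independent route)
        xc = x - x.mean(axis=0)
        sum_r2, sum_p2 = 0.0, 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                rest = [k for k in range(p) if k not in (i, j)]
                zrest = xc[:, rest]
                ri = xc[:, i] - zrest @ np.linalg.lstsq(zrest, xc[:, i], rcond=None)[0]
                rj = xc[:, j] - zrest @ np.linalg.lstsq(zrest, xc[:, j], rcond=None)[0]
                sum_p2 += np.corrcoef(ri, rj)[0, 1] ** 2
                sum_r2 += r[i, j] ** 2
        kmo_expected = sum_r2 / (sum_r2 + sum_p2)
        chi2_expected = -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(r))
        assert d["kmo"] == pytest.approx(kmo_expected, abs=1e-8)
        assert d["bartlett_chi2"] == pytest.approx(chi2_expected, abs=1e-8)


class TestPCAScreen:
    def test_duplicated_pair_both_retained(self):
        out = wt.pca_screen(frame({"a": F1, "b": F1}), loading_threshold=0.5)
        assert out["retained"] == ["a", "b"]

    def test_pure_noise_indicator_dropped(self):
        m = frame({"a": F1, "b": F1, "c": F1, "d": F2, "e": F2, "noise": G})
        out = wt.pca_screen(m, variance_target=0.80, loading_threshold=0.9)
        assert out["retained"] == ["a", "b", "c", "d", "e"]
        assert out["dropped"] == ["noise"]
        assert out["n_components"] == 2

    def test_full_variance_target_keeps_all_components(self):
        m = frame({"a": F1, "b": F2, "c": G})
        out = wt.pca_screen(m, variance_target=1.0, loading_threshold=0.0)
        assert out["n_components"] == 3

    def test_too_aggressive_threshold_errors(self):
        m = frame({"a": F1, "b": F2, "c": G})
        with pytest.raises(ScreeningError):
            wt.pca_screen(m, variance_target=0.4, loading_threshold=1.01)

    def test_retained_fraction_arithmetic(self):
        assert wt.retained_fraction(19, 29) == pytest.approx(100 * 19 / 29)


class TestPCAWeights:
    def test_independent_equal_variance_pair_is_symmetric(self):
        w = wt.pca_weights(frame({"a": F1, "b": G}))
        np.testing.assert_allclose(w.to_numpy(), [0.5, 0.5], atol=1e-12)

    def test_hand_computed_block_structure(self):
        # a == b (eigenvalue 2), c independent (eigenvalue 1): retained
        # components have variance shares 2/3 and 1/3, so the squared-loading
        # mix gives raw weights (2/3, 2/3, 1/3) -> (0.4, 0.4, 0.2).
        w = wt.pca_weights(frame({"a": F1, "b": F1, "c": G}))
        np.testing.assert_allclose(w.to_numpy(), [0.4, 0.4, 0.2], atol=1e-8)

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(40, 4))
        m = frame({f"v{j}": x[:, j] for j in range(4)})
        w = wt.pca_weights(m)
        perm = ["v2", "v0", "v3", "v1"]
        w_perm = wt.pca_weights(m[perm])
        np.testing.assert_allclose(w_perm.to_numpy(), w[perm].to_numpy(), atol=1e-10)


class TestCriticWeights:
    def test_uncorrelated_equal_sigma_pair(self):
        g_scaled = G * (F1.std() / G.std())
        w = wt.critic_weights(frame({"a": F1, "b": g_scaled}))
        np.testing.assert_allclose(w.to_numpy(), [0.5, 0.5], atol=1e-12)

    def test_perfectly_correlated_pair_rejected(self):
        with pytest.raises(WeightingError):
            wt.critic_weights(frame({"a": F1, "b": 2 * F1}))

    def test_matches_direct_formula_loop(self, rng):
        x = rng.uniform(size=(30, 4))
        m = frame({f"v{j}": x[:, j] for j in range(4)})
        w = wt.critic_weights(m)
        r = np.corrcoef(x, rowvar=False)
        c = np.array(
            [x[:, j].std(ddof=1) * sum(1 - r[j, k] for k in range(4)) for j in range(4)]
        )
        np.testing.assert_allclose(w.to_numpy(), c / c.sum(), atol=1e-12)


class TestComprehensiveWeights:
    def test_idempotent_on_identical_inputs(self, rng):
        w = rng.dirichlet(np.ones(5))
        s = pd.Series(w, index=list("abcde"))
        np.testing.assert_allclose(wt.comprehensive_weights(s, s).to_numpy(), w)

    def test_disjoint_mass_averages(self):
        a = pd.Series([1.0, 0.0], index=["x", "y"])
        b = pd.Series([0.0, 1.0], index=["x", "y"])
        np.testing.assert_allclose(
            wt.comprehensive_weights(a, b).to_numpy(), [0.5, 0.5]
        )

    def test_normalization_and_mismatch(self, rng):
        a = pd.Series(rng.dirichlet(np.ones(4)), index=list("abcd"))
        b = pd.Series(rng.dirichlet(np.ones(4)), index=list("abcd"))
        assert wt.comprehensive_weights(a, b).sum() == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(WeightingError):
            wt.comprehensive_weights(a, b.iloc[:3])


def test_scale_invariance_of_weight_pipeline(rng):
    """Affine rescaling of raw indicators cannot change the weights."""
    raw = rng.uniform(1, 5, size=(60, 3))
    codes = ["D9", "D10", "D6"]
    directions = {"D9": 1, "D10": 1, "D6": -1}
    cube = make_cube(raw, codes, directions)
    scaled = make_cube(raw * np.array([3.0, 0.01, 42.0]) + np.array([5.0, -2.0, 0.0]),
                       codes, directions)
    ws_a = wt.compute_weight_set(wt.minmax_normalize(cube))
    ws_b = wt.compute_weight_set(wt.minmax_normalize(scaled))
    np.testing.assert_allclose(
        ws_a.comprehensive.to_numpy(), ws_b.comprehensive.to_numpy(), atol=1e-9
    )


def test_weight_set_vectors_are_distributions():
    """All three weight vectors are nonnegative and sum to one."""
    rng = np.random.default_rng(5)
    cube = make_cube(rng.uniform(size=(80, 4)), ["D1", "D9", "D10", "D6"],
                     {"D1": -1, "D9": 1, "D10": 1, "D6": -1}, years=(2000, 2005))
    ws = wt.compute_weight_set(wt.minmax_normalize(cube))
    for vec in (ws.pca, ws.critic, ws.comprehensive):
        assert (vec >= 0).all()
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
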