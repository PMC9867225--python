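"""Composite index arithmetic, exact natural-breaks optimality, grading."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clsh import health as hl
from clsh import weighting as wt
from clsh.errors import ClassificationError, ContractError
from conftest import make_cube


def make_weight_set(weights: dict) -> wt.WeightSet:
    s = pd.Series(weights, dtype=float)
    return wt.WeightSet(indicators=list(s.index), pca=s, critic=s, comprehensive=s)


def normalized_from(z: np.ndarray, codes, years=(2000,)) -> wt.NormalizedCube:
    cube = make_cube(z, codes, years=years).rename(columns={"value": "z"})
    return wt.NormalizedCube(data=cube, extrema=pd.DataFrame())


class TestCLSHI:
    CODES = ["D1", "D9", "D19"]  # one per layer: pressure, state, response
    W = {"D1": 0.2, "D9": 0.5, "D19": 0.3}

    def test_upper_and_lower_bounds(self):
        for val, expect in ((1.0, 1.0), (0.0, 0.0)):
            nc = normalized_from(np.full((4, 3), val), self.CODES)
            out = hl.compute_clshi(nc, make_weight_set(self.W))
            assert np.allclose(out["clshi"], expect)
            for layer in ("pressure_index", "state_index", "response_index"):
                assert np.allclose(out[layer], expect)

    def test_matches_dot_product_brute_force(self, rng):
        z = rng.uniform(size=(10, 3))
        nc = normalized_from(z, self.CODES)
        out = hl.compute_clshi(nc, make_weight_set(self.W)).sort_values("cell_id")
        w = np.array([self.W[c] for c in self.CODES])
        expected = np.array([sum(z[i, j] * w[j] for j in range(3)) for i in range(10)])
        np.testing.assert_allclose(out["clshi"].to_numpy(), expected, rtol=1e-12)
        # layer sub-index renormalizes within the layer -> equals the z itself
        np.testing.assert_allclose(out["state_index"].to_numpy(), z[:, 1], rtol=1e-12)
        np.testing.assert_allclose(out["raw_pressure"].to_numpy(), 1 - z[:, 0], rtol=1e-12)

    def test_weight_cube_mismatch_rejected(self):
        nc = normalized_from(np.zeros((2, 3)), self.CODES)
        with pytest.raises(ContractError):
            hl.compute_clshi(nc, make_weight_set({"D1": 0.5, "D27": 0.5}))

    def test_monotone_in_positive_indicator(self, rng):
        z = rng.uniform(size=(6, 3))
        bumped = z.copy()
        bumped[:, 1] = np.minimum(bumped[:, 1] + 0.2, 1.0)  # D9 is benefit-direction
        ws = make_weight_set(self.W)
        a = hl.compute_clshi(normalized_from(z, self.CODES), ws)["clshi"]
        b = hl.compute_clshi(normalized_from(bumped, self.CODES), ws)["clshi"]
        assert (b.to_numpy() >= a.to_numpy() - 1e-12).all()


def exhaustive_jenks_ssd(values, k):
    """Minimal within-class SSD over ALL k-partitions of the sorted sample."""
    x = np.sort(np.asarray(values, float))
    n = len(x)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        parts = np.split(x, cuts)
        best = min(best, sum(ssd(p) for p in parts))
    return best


class TestJenks:
    def test_separated_clusters_are_recovered(self):
        brk = hl.jenks_breaks([1, 2, 10, 11, 20, 21], k=3)
        assert brk.bounds == (1.0, 2.0, 11.0, 21.0)
        assert brk.within_ssd == pytest.approx(1.5)  # 0.5 per pair

    def test_k_equals_n_gives_singletons(self):
        brk = hl.jenks_breaks([3.0, 1.0, 2.0, 5.0], k=4)
        assert brk.within_ssd == pytest.approx(0.0)
        assert brk.gvf == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_partition_search(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(2, 6))
        vals = rng.uniform(0, 100, size=n)
        if np.unique(vals).size < k:
            pytest.skip("degenerate draw")
        brk = hl.jenks_breaks(vals, k)
        assert brk.within_ssd == pytest.approx(exhaustive_jenks_ssd(vals, k), abs=1e-9)

    def test_too_few_distinct_values(self):
        with pytest.raises(ClassificationError):
            hl.jenks_breaks([1.0, 1.0, 2.0], k=3)


class TestGrading:
    def test_extremes_and_boundary_rule(self):
        vals = np.array([1, 2, 10, 11, 20, 21], dtype=float)
        brk = hl.jenks_breaks(vals, k=3)
        grades = hl.grade(vals, brk)
        assert grades[np.argmax(vals)] == 1   # best class is I
        assert grades[np.argmin(vals)] == 3   # lowest class (here k=3)
        # value exactly on an interior break belongs to the lower class
        assert hl.grade(np.array([2.0]), brk)[0] == 3
        assert hl.grade(np.array([2.0000001]), brk)[0] == 2

    def test_grades_antitone_in_index(self, rng):
        vals = rng.uniform(size=40)
        brk = hl.jenks_breaks(vals, k=5)
        g = hl.grade(np.sort(vals), brk)
        assert (np.diff(g) <= 0).all()

    def test_out_of_range_clamped_with_warning(self):
        brk = hl.jenks_breaks(np.arange(10.0), k=5)
        with pytest.warns(UserWarning):
            g = hl.grade(np.array([-5.0, 50.0]), brk)
        assert g[0] == 5 and g[1] == 1

    def test_pooled_vs_per_year_modes(self, rng):
        surface = pd.DataFrame(
            {
                "cell_id": np.tile(np.arange(30), 2),
                "year": np.repeat([2000, 2019], 30),
                "clshi": rng.uniform(size=60),
            }
        )
        pooled, brk = hl.grade_surface(surface, k=5, pooled=True)
        assert isinstance(brk, hl.JenksBreaks)
        per_year, brks = hl.grade_surface(surface, k=5, pooled=False)
        assert set(brks) == {2000, 2019}
        assert pooled["grade"].between(1, 5).all()
        assert per_year["grade"].between(1, 5).all()


class TestTimeseriesSummary:
    def _surface(self, clshi, years):
        df = pd.DataFrame({"cell_id": np.arange(len(clshi)), "year": years, "clshi": clshi})
        for c in ("pressure_index", "state_index", "response_index"):
            df[c] = df["clshi"]
        return df

    def test_single_cell_collapses(self):
        out = hl.timeseries_summary(self._surface([0.4], [2000]))
        assert out["clshi_max"].iloc[0] == out["clshi_min"].iloc[0] == out["clshi_mean"].iloc[0]

    def test_mean_within_range(self, rng):
        n = 50
        surf = self._surface(rng.uniform(size=2 * n), np.repeat([2000, 2019], n))
        out = hl.timeseries_summary(surf)
        assert (out["clshi_min"] <= out["clshi_mean"]).all()
        assert (out["clshi_mean"] <= out["clshi_max"]).all()

    def test_planted_decline_is_recovered(self):
        """A generator scenario with declining state/response trends and no
        noise yields a monotonically declining mean index."""
        from clsh.config import (
            GridConfig,
            IndicatorSpec,
            PipelineConfig,
            TruthConfig,
        )
        from clsh.synthetic import generate_scenario
        from clsh.disaggregation import area_weighted_index
        from clsh.indicators import assemble_indicator_cube

        specs = [
            IndicatorSpec(code="D1", mean=300, trend=5.0, noise=0, county_sd=0.1,
                          direction="-", variant="total"),
            IndicatorSpec(code="D19", mean=500, trend=-6.0, noise=0, county_sd=0.1,
                          direction="+", variant="cultivated"),
            IndicatorSpec(code="D14", mean=40, trend=-0.8, noise=0, county_sd=0.1,
                          direction="+", variant="total", kind="percent"),
        ]
        cfg = PipelineConfig(
            grid=GridConfig(n_rows=6, n_cols=6, n_counties=3, fine_factor=4, supersample=2),
            truth=TruthConfig(clusters=[]),
            indicators=specs,
            seed=2,
        )
        scen = generate_scenario(cfg)
        frames = [
            area_weighted_index(scen.panel, scen.overlaps[s.variant], s.code,
                                years=cfg.years)
            for s in specs
        ]
        cube = assemble_indicator_cube(frames, retained=[s.code for s in specs])
        nc = wt.minmax_normalize(cube)
        ws = make_weight_set({"D1": 0.3, "D19": 0.4, "D14": 0.3})
        out = hl.timeseries_summary(hl.compute_clshi(nc, ws))
        means = out.sort_values("year")["clshi_mean"].to_numpy()
        assert (np.diff(means) < 0).all()
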