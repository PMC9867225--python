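import numpy as np
import pandas as pd
import pytest

from clsh.config import GridConfig, PipelineConfig, SpatialConfig
from clsh.synthetic import generate_scenario


def small_pipeline_config(seed: int = 11, n_permutations: int = 199) -> PipelineConfig:
    return PipelineConfig(
        grid=GridConfig(n_rows=10, n_cols=10, n_counties=5, fine_factor=5, supersample=3),
        spatial=SpatialConfig(n_permutations=n_permutations),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_config():
    return small_pipeline_config()


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cube(values: np.ndarray, codes, directions=None, years=(2000,)) -> pd.DataFrame:
    """Long indicator cube from an (n_cells*n_years, n_indicators) matrix."""
    n = values.shape[0] // len(years)
    rows = []
    for j, code in enumerate(codes):
        for yi, year in enumerate(years):
            for c in range(n):
                rows.append((c, year, code, values[yi * n + c, j]))
    cube = pd.DataFrame(rows, columns=["cell_id", "year", "indicator", "value"])
    directions = directions or {c: 1 for c in codes}
    cube["direction"] = cube["indicator"].map(directions)
    return cube
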