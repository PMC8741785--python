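import numpy as np
import pandas as pd
import pytest

from isobase.isoscape import VariogramModel
from isobase.synthetic import SimulationConfig, simulate_tables


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced-size study system for fast module tests."""
    return SimulationConfig(
        seed=7, n_cols=20, n_rows=20, cell_size=1000.0,
        soil_variogram_C=VariogramModel("spherical", 0.05, 0.5, 8000.0),
        soil_variogram_N=VariogramModel("spherical", 0.05, 0.9, 8000.0),
        n_setts=15, n_soil_samples=60,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_tables(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_soil(rng) -> pd.DataFrame:
    """12 random soil points with a smooth + noise value surface."""
    x = rng.uniform(0, 10_000, 12)
    y = rng.uniform(0, 10_000, 12)
    z = -27.0 + 1e-4 * x + rng.normal(0, 0.3, 12)
    return pd.DataFrame({"x": x, "y": y, "d13C": z, "d15N": 5.0 + 2e-4 * y})
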