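import numpy as np
import pandas as pd
import pytest

from karstbeta import ElevationGrid, PlotGeometry, SyntheticConfig
from karstbeta.synthetic import generate_community, generate_dem


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A 200 x 100 m virtual plot, small enough for fast end-to-end tests."""
    return SyntheticConfig(
        seed=42,
        x_extent=200.0,
        y_extent=100.0,
        n_peaks=3,
        n_species=40,
        n_stems_target=4000,
    )


@pytest.fixture(scope="session")
def small_dem(small_config) -> ElevationGrid:
    return generate_dem(small_config)


@pytest.fixture(scope="session")
def small_census(small_config, small_dem) -> pd.DataFrame:
    return generate_community(small_dem, small_config)


@pytest.fixture(scope="session")
def geometry() -> PlotGeometry:
    return PlotGeometry(500.0, 300.0, 10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
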