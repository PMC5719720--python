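import numpy as np
import pytest

from nirscal import synthgen


@pytest.fixture(scope="session")
def default_cfg():
    return synthgen.default_trait_config()


@pytest.fixture(scope="session")
def population():
    """Default synthetic straw population with 7 injected spectral outliers."""
    return synthgen.simulate_population(n=247, n_outliers=7, outlier_magnitude=6.0, seed=11)


@pytest.fixture(scope="session")
def clean_population():
    """Same population without injected outliers."""
    return synthgen.simulate_population(n=247, n_outliers=0, seed=11)


@pytest.fixture(scope="session")
def coarse_library():
    """Component library on an 8 nm grid (261 points) for cheap grid searches."""
    raw = synthgen.load_default_config()
    grid = np.arange(408.0, 2492.0 + 4.0, 8.0)
    return synthgen.ComponentLibrary.from_bands(grid, raw["component_library"])


@pytest.fixture(scope="session")
def small_population(coarse_library):
    """60-sample population on the coarse grid, no outliers, light noise."""
    traits = synthgen.generate_trait_table(60, seed=4)
    return synthgen.generate_spectra(traits, lib=coarse_library, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
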