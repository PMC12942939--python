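import numpy as np
import pytest

from ramanquant.io import SpectralDataset
from ramanquant.simulate import SimConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ds():
    """A tiny deterministic dataset: 10 channels, 5 spectra."""
    rng = np.random.default_rng(7)
    grid = np.linspace(800.0, 809.0, 10)
    intensities = rng.uniform(1.0, 5.0, size=(10, 5))
    targets = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
    return SpectralDataset(wavenumbers=grid, intensities=intensities,
                           targets=targets, unit="mmol/L")


@pytest.fixture(scope="session")
def sim_default():
    """The default synthetic nailfold dataset (curated 75 x 1024) + truth."""
    return generate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def sim_small():
    """A fast low-resolution simulated dataset (256 channels)."""
    cfg = SimConfig(grid_points=256, seed=9)
    return generate(cfg)
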