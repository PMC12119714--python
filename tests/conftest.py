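import numpy as np
import pytest

from dualpet.meta import ProtocolTiming
from dualpet.phantom import (
    NO_NOISE,
    NoiseModel,
    default_grid,
    default_spec,
    simulate_dual_study,
)
from dualpet.volume import Grid


@pytest.fixture(scope="session")
def meta_pair():
    """Protocol metadata for a 70 kg patient at the default one-day timing."""
    return ProtocolTiming().scan_metas(70.0)


@pytest.fixture(scope="session")
def small_grid():
    """A 40^3 lattice at 2 mm (80 mm cube) for cheap geometric tests."""
    return Grid.centered((40, 40, 40), 2.0)


@pytest.fixture(scope="session")
def clinical_grid():
    """A small lattice at the clinical 1.65 mm voxel size."""
    return Grid.centered((32, 32, 32), 1.65)


@pytest.fixture(scope="session")
def coarse_grid():
    """Full-body extent at 4 mm (48^3 = 192 mm cube) for fast cohort tests."""
    return default_grid(48, 4.0)


@pytest.fixture(scope="session")
def noiseless_study():
    """Default-phantom dual study without lesions or noise."""
    return simulate_dual_study(default_spec(), seed=11)


@pytest.fixture(scope="session")
def noisy_study():
    """Default-phantom dual study with the default image-noise model."""
    return simulate_dual_study(default_spec(), noise=NoiseModel(), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
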