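import numpy as np
import pytest

from brixmap.hypercube import Hypercube, WavelengthAxis
from brixmap.synthetic import generate_dataset, generate_scene, make_library


@pytest.fixture(scope="session")
def library():
    return make_library()


@pytest.fixture(scope="session")
def scene():
    """One default 128x128 labelled scene (cube, truth)."""
    return generate_scene(seed=7)


@pytest.fixture(scope="session")
def dataset():
    """Flat spectra-vs-Brix table, n=400, Brix noise 0.2."""
    return generate_dataset(n_samples=400, noise_sd=0.2, seed=7)


@pytest.fixture
def small_cube():
    rng = np.random.default_rng(0)
    axis = WavelengthAxis(np.linspace(913.0, 2166.0, 10))
    return Hypercube(rng.uniform(0.1, 1.5, size=(4, 4, 10)), axis)
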