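import numpy as np
import pytest

from leapscan import make_phantom


@pytest.fixture(scope="session")
def cell_phantom_64():
    return make_phantom("cell", 64, 64, seed=1)


@pytest.fixture(scope="session")
def homogeneous_64():
    return make_phantom("homogeneous", 64, 64, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
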