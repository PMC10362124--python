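import numpy as np
import pytest

from hyperfilt import make_shapes_phantom


@pytest.fixture(scope="session")
def shapes_phantom():
    """Default 256x256 geometric phantom, shared read-only across tests."""
    return make_shapes_phantom(256, 256, seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    return make_shapes_phantom(128, 128, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
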