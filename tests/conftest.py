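import numpy as np
import pytest

from somaseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 64^3 phantom pair shared across tests."""
    return generate_phantom(PhantomConfig(seed=3))


@pytest.fixture(scope="session")
def tiny_phantom():
    """A small, quick-to-segment phantom (48^3, 3 somata)."""
    cfg = PhantomConfig(
        shape=(48, 48, 48), n_somata=3, radius_range=(5, 7), seed=11
    )
    return generate_phantom(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
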