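import numpy as np
import pytest

from choroseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_sample():
    """One deterministic mid-size phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def clean_phantom_sample():
    """Noise-free phantom (speckle 0) for exact-value checks."""
    return generate_phantom(PhantomSpec(seed=7, speckle_level=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
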