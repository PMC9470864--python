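import numpy as np
import pytest

from ossiseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_pair(default_spec):
    """One deterministic default phantom (image, labels), shared across tests."""
    return generate_phantom(default_spec, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
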