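import numpy as np
import pytest

from cagsnet.preprocessing import preprocess_case
from cagsnet.synthetic import generate_phantom, random_spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    """One deterministic 32-cubed phantom with all three tumor labels."""
    spec = random_spec(np.random.default_rng(7), shape=(32, 32, 32),
                       case_id="p0")
    vol = generate_phantom(spec)
    assert all((vol.labels == c).any() for c in (1, 2, 4))
    return vol


@pytest.fixture(scope="session")
def case32(phantom32):
    """The phantom preprocessed at its native 32-cubed grid."""
    return preprocess_case(phantom32, target_shape=(32, 32, 32))
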