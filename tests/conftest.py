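import numpy as np
import pytest

from fiberfold.synthgen import SyntheticSpec, generate_pattern


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def symmetric_pattern():
    """Noise-free four-fold-symmetric pattern with its ground truth."""
    spec = SyntheticSpec(shape=(256, 256), S10=50.0)
    return generate_pattern(spec)
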