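import numpy as np
import pytest

from rnaloops import gen_core


@pytest.fixture(scope="session")
def default_core():
    """One deterministic synthetic core shared across tests."""
    return gen_core(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
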