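import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_binary(rng):
    """Factory for random binary images with a given black fraction."""

    def make(h=12, w=12, p_black=0.5):
        return (rng.random((h, w)) >= p_black).astype(np.uint8)

    return make


@pytest.fixture
def random_gray(rng):
    def make(h=12, w=12, high=256):
        return rng.integers(0, high, (h, w)).astype(np.uint8)

    return make
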