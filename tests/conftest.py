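import numpy as np
import pytest

from tetraseg.likelihood import counts_to_gl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def indicator_gl():
    """GL matrix equivalent to known counts (130, 100, 10, 0, 0)."""
    x = np.array([130, 100, 10, 0, 0])
    return x, counts_to_gl(x)
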