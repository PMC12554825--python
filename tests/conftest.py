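import numpy as np
import pytest

from koperator import SquareMatrix, make_random_symmetric


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def g_pair():
    """The worked 2x2 pair used across operator tests."""
    g = SquareMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]))
    gk = SquareMatrix(np.array([[1.0, 0.2], [0.2, 1.0]]))
    return gk, g


@pytest.fixture
def random_connectome():
    return make_random_symmetric(6, (0.0, 1.0), unit_diagonal=True, seed=42)
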