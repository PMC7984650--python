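import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_regression(rng):
    """Small dense regression problem with a sparse true weight vector."""
    X = rng.standard_normal((60, 25))
    w = np.zeros(25)
    w[[2, 7, 11]] = [1.5, -2.0, 0.8]
    y = X @ w + 0.4 * rng.standard_normal(60)
    return X, y, w
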