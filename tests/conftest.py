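import numpy as np
import pytest

from lctgsa import center_scale


@pytest.fixture
def rng():
    return np.random.default_rng(20240803)


@pytest.fixture
def small_blocks(rng):
    """A standardized (X, Y) pair with a mild linear association."""
    n, p, q = 15, 4, 3
    X_raw = rng.normal(size=(n, p))
    Y_raw = X_raw[:, :2] @ rng.normal(size=(2, q)) * 0.5 + rng.normal(size=(n, q))
    return center_scale(X_raw), center_scale(Y_raw)
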