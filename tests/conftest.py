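import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """Small random integer image for brute-force LBP oracles."""
    return rng.integers(0, 256, size=(9, 9)).astype(float)


@pytest.fixture
def labeled_blobs(rng):
    """Three well-separated Gaussian blobs in 5-D with labels."""
    centers = np.array(
        [[6, 0, 0, 0, 0], [0, 6, 0, 0, 0], [0, 0, 6, 0, 0]], dtype=float
    )
    X = np.vstack([rng.normal(c, 1.0, size=(15, 5)) for c in centers])
    y = np.repeat([0, 1, 2], 15)
    return X, y
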