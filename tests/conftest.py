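import numpy as np
import pytest
from hypothesis import settings

from progenyclust import RunConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A light configuration for structural (non-benchmark) tests."""
    return RunConfig(k_min=2, k_max=4, n_progenies=4, n_repeats=10, n_references=2)


@pytest.fixture
def blobs_2d(rng):
    """Two tight, far-separated 2-D clusters of 15 points each."""
    a = rng.normal([0.0, 0.0], 0.1, size=(15, 2))
    b = rng.normal([10.0, 10.0], 0.1, size=(15, 2))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 15)
    return X, labels
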