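import numpy as np
import pytest

from ssps.data import PriorConfidences, TimeCourseSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_data(rng):
    """3 variables, 4 courses of 8 timepoints: the toy inference scale."""
    courses = [rng.normal(size=(8, 3)) for _ in range(4)]
    return TimeCourseSet(["a", "b", "c"], courses)


@pytest.fixture
def small_prior(rng):
    conf = rng.random((3, 3))
    return PriorConfidences(["a", "b", "c"], conf)
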