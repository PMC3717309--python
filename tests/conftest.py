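import numpy as np
import pytest

from helpers import phantom, population_features, small_spec


@pytest.fixture(scope="session")
def default_phantom():
    """One mid-size proliferating-like field shared across read-only tests."""
    stack, truth, rois = phantom(10, small_spec(), seed=11, shape=(18, 192, 192))
    return stack, truth, rois


@pytest.fixture(scope="session")
def default_features(default_phantom):
    stack, truth, rois = default_phantom
    return population_features(stack, rois)
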