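import numpy as np
import pytest

from dynattractor import ModelParams


@pytest.fixture
def params():
    """Table defaults."""
    return ModelParams()


@pytest.fixture
def small_params():
    """A small network for fast structural tests."""
    return ModelParams(N=20, gamma=0.1)


def assert_paradigms_equal(a, b):
    assert list(a.patterns) == list(b.patterns)
    for k in a.patterns:
        np.testing.assert_array_equal(a.patterns[k], b.patterns[k])
    assert a.trains == b.trains
    assert a.warmup == b.warmup
    assert a.post == b.post
    assert a.probe_times == b.probe_times
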