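import numpy as np
import pytest

from ogt.annotation_io import Annotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotation(values, annotator_id="a", stimulus_id="stim", rate_hz=1.0):
    return Annotation(annotator_id, stimulus_id, rate_hz, np.asarray(values, dtype=float))


@pytest.fixture
def wiggly_signal(rng):
    """A smooth non-monotone signal long enough for alignment tests."""
    x = np.cumsum(rng.normal(0, 1.0, 50))
    return np.convolve(x, np.ones(3) / 3, mode="same")
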