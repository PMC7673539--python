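import numpy as np
import pytest

from tactus import ModelConfig, OnsetSequence


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def worked_example_onsets():
    """The isochronous passage r_k = 1.04167 + 500 k ms, k = 0..4.

    Five onsets at a 500 ms pulse with a 1.04167 ms phase; the tracker
    states on this passage have known scores (2/3, 1/2, 3/5 for the
    1000 ms-period hypothesis; 1 for the 500 ms one).
    """
    return OnsetSequence(1.04167 + 500.0 * np.arange(5))


@pytest.fixture
def iso500():
    """Plain isochronous fixture: 20 onsets, 500 ms apart, phase 0."""
    return OnsetSequence(500.0 * np.arange(20))
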