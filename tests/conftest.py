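import numpy as np
import pytest

from tespread.annotation import TeRecord
from tespread.hmd import HmdTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_track():
    """100-kb chromosome of constant HMD 1.0, nothing missing."""
    n = 100_000 // 25
    return HmdTrack("chr1", np.ones(n), np.zeros(n, dtype=bool))


@pytest.fixture
def mid_te():
    """A 2-kb TE in the middle of the 100-kb flat track."""
    return TeRecord("te1", "chr1", 49_000, 51_000)
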