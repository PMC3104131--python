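import numpy as np
import pytest

from cnvcall import ProbeTrack, RunConfig, StateTrack
from cnvcall.core import STATE_DECREASED, STATE_INCREASED, STATE_NORMAL

STATE_CODES = {"D": STATE_DECREASED, "N": STATE_NORMAL, "I": STATE_INCREASED}


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


def make_track(positions, values, chrom="chr1", sample_id="test") -> ProbeTrack:
    return ProbeTrack(sample_id, {chrom: (np.asarray(positions), np.asarray(values, float))})


def make_states(pattern: str, chrom="chr1") -> StateTrack:
    """StateTrack from a string like 'NNIIDN' (N=normal, I=increased, D=decreased)."""
    return StateTrack({chrom: np.array([STATE_CODES[c] for c in pattern], dtype=np.int8)})
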