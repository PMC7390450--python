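import numpy as np
import pytest

from damsleep.dam_io import ActivityTrace
from damsleep.protocol import make_schedule


@pytest.fixture(scope="session")
def ld():
    return make_schedule("LD")


@pytest.fixture(scope="session")
def dms():
    return make_schedule("DMS")


@pytest.fixture(scope="session")
def dls():
    return make_schedule("DLS")


@pytest.fixture(scope="session")
def dd():
    return make_schedule("DD")


@pytest.fixture
def make_trace():
    """Factory: build a 1-min-bin ActivityTrace from a count sequence."""

    def _make(counts, t0_zt=0.0, fly_id="f1", channel=1, light=None, meta=None):
        counts = np.asarray(counts, dtype=np.int64)
        if light is None:
            light = np.zeros(len(counts), dtype=bool)
        return ActivityTrace(fly_id=fly_id, monitor_channel=channel, t0_zt=t0_zt,
                             bin_width=1, counts=counts, light=light,
                             meta=meta or {})

    return _make


def brute_force_zero_runs(counts, min_len=5):
    """Independent maximal-zero-run scanner (plain loop, no numpy tricks)."""
    runs = []
    start = None
    for i, c in enumerate(counts):
        if c == 0:
            if start is None:
                start = i
        else:
            if start is not None:
                if i - start >= min_len:
                    runs.append((start, i))
                start = None
    if start is not None and len(counts) - start >= min_len:
        runs.append((start, len(counts)))
    return runs
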