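import numpy as np
import pytest

from mssc import ChannelSet, ImageGrid, make_schedule


def grid(arr) -> ImageGrid:
    return ImageGrid(np.asarray(arr, dtype=float))


def mono(arr) -> ChannelSet:
    g = grid(arr)
    return ChannelSet(channels={"L": g}, weights={"L": 1.0})


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def noise16(rng):
    return grid(rng.uniform(0, 1, (16, 16)))


@pytest.fixture
def sched64():
    return make_schedule(64, 10)
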