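import numpy as np
import pytest
from hypothesis import settings

from dcmigration.datatypes import Track, TrackSet

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def straight_track():
    """Constant-velocity track along +y at 5 µm/min, sampled every 2 min."""
    times = np.arange(0, 62, 2.0)
    pos = np.column_stack([np.zeros_like(times), 5.0 * times])
    return Track("straight", times, pos)


@pytest.fixture
def stationary_track():
    times = np.arange(0, 20, 2.0)
    return Track("still", times, np.full((len(times), 2), 3.5))


@pytest.fixture
def small_trackset():
    times = np.arange(0.0, 61.0)
    straight = Track(
        "straight1", times, np.column_stack([np.zeros_like(times), 5.0 * times])
    )
    zig = Track(
        "zigzag",
        np.array([0.0, 1.0, 2.0]),
        np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]]),
    )
    return TrackSet([straight, zig], frame_interval=1.0, condition="test")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
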