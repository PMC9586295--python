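import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from gyrowall import SyntheticSpec, Trajectory
from gyrowall.synth import make_fields, generate_tracks


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_track():
    """Constant-velocity track: 10 um/frame along +x at 10 fps."""
    n = 30
    times = np.arange(n) * 0.1
    pos = np.column_stack([10.0 * np.arange(n), np.full(n, 500.0)])
    return Trajectory("straight", times, pos, 0.1)


def circle_track(radius=50.0, rate=0.5, dt=0.1, n=200, track_id="circle"):
    t = np.arange(n) * dt
    pos = np.column_stack([radius * np.cos(rate * t), 500.0 + radius * np.sin(rate * t)])
    return Trajectory(track_id, t, pos, dt)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Small default-condition synthetic track set with ground truth."""
    spec = SyntheticSpec(seed=42)
    fields = make_fields(spec)
    tracks, truth = generate_tracks(fields, spec, n_tracks=60, duration=30.0)
    return spec, fields, tracks, truth
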