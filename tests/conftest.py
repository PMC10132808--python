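import numpy as np
import pandas as pd
import pytest

from sptmem.tracks import TrajectorySet


def make_track(frames, xy, track_id=0, frame_interval=0.02) -> TrajectorySet:
    """Build a one-track TrajectorySet from explicit frames and positions."""
    xy = np.asarray(xy, float)
    df = pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.asarray(frames, int),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
        }
    )
    return TrajectorySet(df, frame_interval=frame_interval)


def random_walk_track(n_points, step_sigma=0.1, seed=0, frame_interval=0.02) -> TrajectorySet:
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0.0, step_sigma, size=(n_points, 2)), axis=0)
    return make_track(np.arange(n_points), xy, frame_interval=frame_interval)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
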