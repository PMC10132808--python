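"""LAP linker: gating, gap closing, ground-truth recovery, invariants."""

import numpy as np
import pandas as pd
import pytest

from sptmem import (
    SimulationConfig,
    filter_tracks,
    link_detections,
    read_trackmate_spots,
    render_detections,
    simulate_trajectories,
)


def _det(rows):
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


def _partition(linked, detections):
    """Map each linked track to the set of truth ids of its detections."""
    merged = linked.data.merge(detections, on=["frame", "x_um", "y_um"], how="left")
    return merged.groupby("track_id")["truth_id"]


def test_two_separated_stationary_particles():
    rows = [(f, x, 0.0) for f in range(10) for x in (0.0, 5.0)]
    linked = link_detections(_det(rows))
    assert linked.n_tracks == 2
    assert sorted(linked.lengths()) == [10, 10]


def test_gap_closing_bridges_one_missing_frame():
    rows = [(f, 0.1 * f, 0.0) for f in range(10) if f != 5]
    linked = link_detections(_det(rows))
    assert linked.n_tracks == 1
    frames = linked.data["frame"].tolist()
    assert frames == [0, 1, 2, 3, 4, 6, 7, 8, 9]


def test_jump_beyond_gate_splits_track():
    rows = [(f, 0.0, 0.0) for f in range(5)] + [(f, 2.0, 0.0) for f in range(5, 10)]
    linked = link_detections(_det(rows), max_gap=0)
    assert linked.n_tracks == 2


def test_gap_not_closed_beyond_max_gap():
    # 3 missing frames > max_gap=2
    rows = [(f, 0.0, 0.0) for f in list(range(5)) + list(range(8, 12))]
    linked = link_detections(_det(rows), max_gap=2)
    assert linked.n_tracks == 2


def test_empty_table_returns_empty_set():
    linked = link_detections(_det([]))
    assert linked.n_tracks == 0


def test_negative_parameters_rejected():
    with pytest.raises(ValueError):
        link_detections(_det([(0, 0.0, 0.0)]), max_link_dist=-1.0)
    with pytest.raises(ValueError):
        link_detections(_det([(0, 0.0, 0.0)]), max_gap=-1)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ground_truth_recovery_on_sparse_noiseless_movies(seed):
    # density 12 / (30x30) ~ 0.013 um^-2, well under the sparse regime
    cfg = SimulationConfig(n_particles=12, n_frames=30, fov=(30, 30),
                          states=[("s", 0.5)], boundary="none", seed=seed)
    tracks, _ = simulate_trajectories(cfg)
    det = render_detections(tracks, 0.0, 0.0, seed=1)
    linked = link_detections(det.drop(columns=["truth_id", "intensity"]))
    assert linked.n_tracks == tracks.n_tracks
    grp = _partition(linked, det)
    assert (grp.nunique() == 1).all()  # every track pure
    assert len(linked.data) == len(det)  # every detection assigned


def test_gap_bridged_tracks_match_truth():
    cfg = SimulationConfig(n_particles=10, n_frames=20, fov=(30, 30),
                          states=[("s", 0.5)], boundary="none", seed=4)
    tracks, _ = simulate_trajectories(cfg)
    det = render_detections(tracks, 0.0, 0.0, seed=1)
    det = det[det["frame"] != 5].reset_index(drop=True)  # one gap per track
    linked = link_detections(det.drop(columns=["truth_id", "intensity"]))
    assert linked.n_tracks == 10
    assert sorted(linked.lengths()) == [19] * 10
    grp = _partition(linked, det)
    assert (grp.nunique() == 1).all()


def test_partition_property():
    cfg = SimulationConfig(n_particles=20, n_frames=25, fov=(25, 25),
                          states=[("s", 1.0)], seed=7)
    tracks, _ = simulate_trajectories(cfg)
    det = render_detections(tracks, 0.01, 0.1, seed=2)
    linked = link_detections(det.drop(columns=["truth_id", "intensity"]))
    assert linked.lengths().sum() == len(det)  # no detection discarded or reused
    # no duplicated assignments
    assert not linked.data.duplicated(subset=["frame", "x_um", "y_um"]).any()


def test_permutation_invariance_within_frames():
    cfg = SimulationConfig(n_particles=15, n_frames=20, fov=(25, 25),
                          states=[("s", 1.0)], boundary="none", seed=9)
    tracks, _ = simulate_trajectories(cfg)
    det = render_detections(tracks, 0.0, 0.0, seed=1).drop(columns=["intensity"])
    rng = np.random.default_rng(0)
    shuffled = det.iloc[rng.permutation(len(det))].reset_index(drop=True)
    p1 = {frozenset(map(tuple, g[["frame", "truth_id"]].values))
          for _, g in link_detections(det).data.merge(det, on=["frame", "x_um", "y_um"])
          .groupby("track_id")}
    p2 = {frozenset(map(tuple, g[["frame", "truth_id"]].values))
          for _, g in link_detections(shuffled).data.merge(det, on=["frame", "x_um", "y_um"])
          .groupby("track_id")}
    assert p1 == p2


class TestFilterTracks:
    def _tracks(self):
        rows = []
        for tid, length in enumerate([1, 2, 5]):
            rows += [(tid, f, float(tid), 0.0) for f in range(length)]
        df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
        from sptmem.tracks import TrajectorySet

        return TrajectorySet(df)

    def test_min_length_one_is_identity(self):
        ts = self._tracks()
        assert filter_tracks(ts, 1).data.equals(ts.data)

    def test_min_length_three_keeps_one(self):
        assert filter_tracks(self._tracks(), 3).n_tracks == 1

    def test_filter_everything_warns(self):
        with pytest.warns(UserWarning):
            out = filter_tracks(self._tracks(), 99)
        assert out.n_tracks == 0

    def test_invalid_min_length(self):
        with pytest.raises(ValueError):
            filter_tracks(self._tracks(), 0)


def test_trackmate_import_with_pixel_conversion(tmp_path):
    df = pd.DataFrame(
        {
            "LABEL": ["ID1", "ID2", "ID3", "ID4"],
            "TRACK_ID": [0, 0, 1, -1],
            "FRAME": [0, 1, 0, 0],
            "POSITION_X": [10.0, 12.0, 50.0, 1.0],
            "POSITION_Y": [10.0, 10.0, 50.0, 1.0],
        }
    )
    path = tmp_path / "spots.csv"
    df.to_csv(path, index=False)
    ts = read_trackmate_spots(path, frame_interval=0.02, pixel_size_um=0.1)
    assert ts.n_tracks == 2  # TRACK_ID -1 (unassigned) dropped
    assert ts.data["x_um"].max() == pytest.approx(5.0)
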