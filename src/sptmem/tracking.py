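"""Linear-assignment-problem (LAP) particle linking with gap closing.

Detections in consecutive frames are matched one-to-one by minimizing total
squared displacement, gated at a maximum linking distance; the assignment is
solved exactly with the Hungarian algorithm rather than greedy
nearest-neighbour, so the result is deterministic and order-independent. A
second pass re-joins terminated track ends to tracks that start 2..max_gap+1
frames later within a gap distance, shortest gap first — the same rule set as
the "simple LAP tracker" used for single-molecule TIRF movies (linking
distance 1.5 µm, frame gap 2, gap distance 1.5 µm by default).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .tracks import TrajectorySet

logger = logging.getLogger(__name__)

__all__ = ["LAPTracker", "link_detections", "filter_tracks"]

_BIG = 1e12


def _gated_matching(a_xy: np.ndarray, b_xy: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """One-to-one matching minimizing total squared distance within a gate.

    Uses the standard augmented cost matrix: linking block C (squared
    distances, forbidden beyond the gate), plus per-item "no link" diagonal
    blocks priced so that any within-gate link is preferred over leaving both
    endpoints unlinked. Returns matched (index in a, index in b) pairs.
    """
    n, m = len(a_xy), len(b_xy)
    if n == 0 or m == 0:
        return []
    d2 = cdist(a_xy, b_xy, "sqeuclidean")
    gate = max_dist * max_dist
    c = np.where(d2 <= gate + 1e-12, d2, _BIG)
    b_cost = 0.5 * gate + 1e-9  # link accepted iff cheaper than two "no link"s
    full = np.full((n + m, m + n), _BIG)
    full[:n, :m] = c
    full[:n, m:] = np.where(np.eye(n, dtype=bool), b_cost, _BIG)
    full[n:, :m] = np.where(np.eye(m, dtype=bool), b_cost, _BIG)
    full[n:, m:] = 0.0  # unused dummies pair freely
    rows, cols = linear_sum_assignment(full)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if i < n and j < m and c[i, j] < _BIG]


class LAPTracker(BaseEstimator):
    """Configurable LAP linker; ``link`` (alias ``transform``) builds tracks.

    Parameters mirror the tracking settings of single-molecule movie
    analysis: ``max_link_dist`` gates frame-to-frame links, ``max_gap`` is
    the number of consecutive missed frames that may be bridged, and
    ``max_gap_dist`` gates the bridging displacement.
    """

    def __init__(
        self,
        max_link_dist: float = 1.5,
        max_gap: int = 2,
        max_gap_dist: float = 1.5,
        frame_interval: float = 0.02,
    ):
        self.max_link_dist = max_link_dist
        self.max_gap = max_gap
        self.max_gap_dist = max_gap_dist
        self.frame_interval = frame_interval

    def link(self, detections: pd.DataFrame) -> TrajectorySet:
        if self.max_link_dist < 0 or self.max_gap_dist < 0:
            raise ValueError("linking distances must be >= 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        cols = {"frame", "x_um", "y_um"}
        if not cols.issubset(detections.columns):
            raise ValueError(f"detection table needs columns {sorted(cols)}")
        det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
        if len(det) == 0:
            empty = pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
            return TrajectorySet(empty, frame_interval=self.frame_interval)

        frames = det["frame"].to_numpy().astype(int)
        xy = det[["x_um", "y_um"]].to_numpy(float)
        by_frame: dict[int, np.ndarray] = {
            f: np.nonzero(frames == f)[0] for f in np.unique(frames)
        }

        # pass 1: frame-to-frame linking
        tracks: list[list[int]] = []  # lists of detection row indices
        active: dict[int, int] = {}  # detection row of a track's last point -> track idx
        prev_rows: np.ndarray | None = None
        prev_frame: int | None = None
        for f in sorted(by_frame):
            rows = by_frame[f]
            if prev_rows is not None and f == prev_frame + 1:
                pairs = _gated_matching(xy[prev_rows], xy[rows], self.max_link_dist)
            else:
                pairs = []
            matched_b = set()
            for ia, ib in pairs:
                t = active.pop(int(prev_rows[ia]))
                tracks[t].append(int(rows[ib]))
                active[int(rows[ib])] = t
                matched_b.add(ib)
            for ib, row in enumerate(rows):
                if ib not in matched_b:
                    tracks.append([int(row)])
                    active[int(row)] = len(tracks) - 1
            # tracks ending before f stay terminated; drop their active entries
            active = {r: t for r, t in active.items() if frames[r] == f}
            prev_rows, prev_frame = rows, f

        # pass 2: gap closing, shortest gap first
        merged_into: dict[int, int] = {}
        for gap in range(2, self.max_gap + 2):  # frame difference 2..max_gap+1
            ends: dict[int, list[int]] = {}
            starts: dict[int, list[int]] = {}
            for t, rows_t in enumerate(tracks):
                if t in merged_into or not rows_t:
                    continue
                ends.setdefault(int(frames[rows_t[-1]]), []).append(t)
                starts.setdefault(int(frames[rows_t[0]]), []).append(t)
            for f_end in sorted(ends):
                cand_starts = [t for t in starts.get(f_end + gap, []) if t not in merged_into]
                cand_ends = [t for t in ends[f_end] if t not in merged_into and tracks[t]]
                if not cand_starts or not cand_ends:
                    continue
                e_xy = np.array([xy[tracks[t][-1]] for t in cand_ends])
                s_xy = np.array([xy[tracks[t][0]] for t in cand_starts])
                for ia, ib in _gated_matching(e_xy, s_xy, self.max_gap_dist):
                    te, ts = cand_ends[ia], cand_starts[ib]
                    if te == ts or ts in merged_into or te in merged_into:
                        continue
                    tracks[te].extend(tracks[ts])
                    tracks[ts] = []
                    merged_into[ts] = te
                    # the merged track's new end may seed a later gap pass
                    ends.setdefault(int(frames[tracks[te][-1]]), []).append(te)

        out_rows = []
        new_id = 0
        order = sorted(
            (t for t in range(len(tracks)) if tracks[t]),
            key=lambda t: (frames[tracks[t][0]], tracks[t][0]),
        )
        for t in order:
            for r in tracks[t]:
                out_rows.append((new_id, int(frames[r]), xy[r, 0], xy[r, 1]))
            new_id += 1
        df = pd.DataFrame(out_rows, columns=["track_id", "frame", "x_um", "y_um"])
        return TrajectorySet(df, frame_interval=self.frame_interval)

    # transformer-style alias so the tracker composes with sklearn pipelines
    def transform(self, detections: pd.DataFrame) -> TrajectorySet:
        return self.link(detections)

    def fit(self, X=None, y=None) -> "LAPTracker":  # stateless
        return self


def link_detections(
    detections: pd.DataFrame,
    max_link_dist: float = 1.5,
    max_gap: int = 2,
    max_gap_dist: float = 1.5,
    frame_interval: float = 0.02,
) -> TrajectorySet:
    """Link a detection table (frame, x_um, y_um) into trajectories."""
    tracker = LAPTracker(
        max_link_dist=max_link_dist,
        max_gap=max_gap,
        max_gap_dist=max_gap_dist,
        frame_interval=frame_interval,
    )
    return tracker.link(detections)


def filter_tracks(tracks: TrajectorySet, min_length: int = 1) -> TrajectorySet:
    """Keep tracks with at least ``min_length`` localizations.

    The default of 1 applies no filtering: quasi-immobile and short-lived
    molecules are part of the analyzed population.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    lengths = tracks.lengths()
    keep = lengths.index[lengths >= min_length]
    n_dropped = tracks.n_tracks - len(keep)
    logger.info("filter_tracks: kept %d of %d tracks", len(keep), tracks.n_tracks)
    if len(keep) == 0 and tracks.n_tracks > 0:
        warnings.warn(
            f"min_length={min_length} removed every track", UserWarning, stacklevel=2
        )
    df = tracks.data[tracks.data["track_id"].isin(keep)].reset_index(drop=True)
    return TrajectorySet(df, frame_interval=tracks.frame_interval)
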