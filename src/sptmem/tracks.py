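"""Trajectory containers and track-table I/O.

All positions are in micrometres and all times in seconds throughout the
package; pixel units are converted at import boundaries only (see
:func:`read_trackmate_spots`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


@dataclass
class TrajectorySet:
    """A set of single-particle trajectories sharing one frame interval.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format table with columns ``track_id``, ``frame``, ``x_um``,
        ``y_um`` (an optional ``state`` column is carried through untouched,
        e.g. for simulator ground truth). Frames are integer and strictly
        increasing within each track.
    frame_interval : float
        Time between consecutive frames, in seconds.
    """

    data: pd.DataFrame
    frame_interval: float = 0.02

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        self.data = self.data.sort_values(["track_id", "frame"], kind="stable").reset_index(
            drop=True
        )
        frames = self.data["frame"].to_numpy()
        tids = self.data["track_id"].to_numpy()
        same = tids[1:] == tids[:-1]
        if np.any(same & (np.diff(frames) <= 0)):
            raise ValueError("frames must be strictly increasing within a track")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def __len__(self) -> int:
        return self.n_tracks

    def lengths(self) -> pd.Series:
        """Number of localizations per track."""
        return self.data.groupby("track_id").size()

    def itertracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        yield from self.data.groupby("track_id", sort=True)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval: float = 0.02) -> "TrajectorySet":
        df = pd.read_csv(path)
        return cls(df, frame_interval=frame_interval)


def read_trackmate_spots(
    path: str | Path,
    frame_interval: float = 0.02,
    pixel_size_um: float = 1.0,
) -> TrajectorySet:
    """Import a TrackMate spots-table CSV as a :class:`TrajectorySet`.

    TrackMate exports spot tables with columns ``TRACK_ID``, ``FRAME``,
    ``POSITION_X``, ``POSITION_Y`` and, in recent versions, up to three extra
    non-numeric header rows below the column names; those rows are dropped.
    Positions are multiplied by ``pixel_size_um`` so that the returned
    trajectories are in micrometres (use 1.0 if the export is already
    calibrated in µm).
    """
    df = pd.read_csv(path)
    required = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"TrackMate spots file missing columns: {missing}")
    df = df[required].apply(pd.to_numeric, errors="coerce").dropna()
    out = pd.DataFrame(
        {
            "track_id": df["TRACK_ID"].astype(int),
            "frame": df["FRAME"].astype(int),
            "x_um": df["POSITION_X"].astype(float) * pixel_size_um,
            "y_um": df["POSITION_Y"].astype(float) * pixel_size_um,
        }
    )
    # spots not assigned to any track carry TRACK_ID = -1 in some exports
    out = out[out["track_id"] >= 0].reset_index(drop=True)
    return TrajectorySet(out, frame_interval=frame_interval)


@dataclass
class ValidationReport:
    """Result of :func:`validate_tracks`."""

    ok: bool
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_rows: int = 0
    n_tracks: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"rows={self.n_rows} tracks={self.n_tracks} ok={self.ok}"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate_tracks(path: str | Path, fov_um: float | None = None) -> ValidationReport:
    """Check a track CSV for schema and unit problems.

    Verifies the column schema, integer non-negative frames, finite
    coordinates, absence of duplicated ``(track_id, frame)`` rows, and — when
    ``fov_um`` is given — warns when coordinates look like raw pixel indices
    (values far beyond the field of view in µm).
    """
    report = ValidationReport(ok=True)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable file
        report.ok = False
        report.errors.append(f"unreadable file: {exc}")
        return report
    report.n_rows = len(df)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        report.ok = False
        report.errors.append(f"missing columns: {missing}")
        return report
    report.n_tracks = df["track_id"].nunique()

    frames = df["frame"].to_numpy()
    if not np.issubdtype(frames.dtype, np.integer):
        if not np.allclose(frames, np.round(frames)):
            report.errors.append("frame column is not integer-valued")
        frames = np.round(frames).astype(int)
    if (frames < 0).any():
        report.errors.append("negative frame indices present")

    xy = df[["x_um", "y_um"]].to_numpy(float)
    if not np.isfinite(xy).all():
        report.errors.append("non-finite coordinates present")

    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]  # 1-based incl. header
        report.errors.append(f"duplicated (track_id, frame) rows at lines {rows}")

    for tid, grp in df.groupby("track_id"):
        f = grp["frame"].to_numpy()
        if len(f) > 1 and not (np.diff(np.sort(f)) > 0).all():
            report.errors.append(f"track {tid}: frames not strictly increasing")
            break

    if fov_um is not None and np.isfinite(xy).all() and len(xy):
        if np.nanmax(np.abs(xy)) > 5.0 * fov_um:
            report.warnings.append(
                "coordinates greatly exceed the stated field of view "
                f"({fov_um} um); values may be in pixels — convert with a "
                "pixel-size factor at import"
            )
    report.ok = not report.errors
    return report
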