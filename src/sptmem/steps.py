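"""Step-size (jump-distance) extraction and histogramming.

A "step" is the displacement magnitude r between two localizations of the
same track separated by exactly ``delay_frames`` frames (delay time
``tau = delay_frames * frame_interval``). To avoid over-counting correlated
displacements, the default mode takes non-overlapping frame pairs anchored at
each track's first frame (0→k, k→2k, ...), which yields exactly
``floor((L - 1) / k)`` steps for a gap-free track of L points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import TrajectorySet

logger = logging.getLogger(__name__)

__all__ = ["StepHistogram", "compute_steps", "build_histogram"]

STEP_COLUMNS = ["r_um", "delay_frames", "tau_s"]


def compute_steps(
    tracks: TrajectorySet,
    delay_frames: int,
    non_overlapping: bool = True,
) -> pd.DataFrame:
    """Displacement magnitudes at one delay, as a table (r_um, delay_frames, tau_s).

    Frame gaps introduced by gap-closing yield no step across the missing
    interval: a pair contributes only when both endpoint frames exist at the
    exact spacing.
    """
    if delay_frames < 1:
        raise ValueError("delay_frames must be >= 1")
    k = int(delay_frames)
    tau = k * tracks.frame_interval
    rs: list[np.ndarray] = []
    for _, grp in tracks.itertracks():
        f = grp["frame"].to_numpy()
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        if len(f) < 2:
            continue
        if non_overlapping:
            anchors = f[0] + k * np.arange((f[-1] - f[0]) // k + 1)
            idx = np.searchsorted(f, anchors)
            idx = np.clip(idx, 0, len(f) - 1)
            present = f[idx] == anchors
            pair = present[:-1] & present[1:]
            i0, i1 = idx[:-1][pair], idx[1:][pair]
        else:
            targets = f + k
            j = np.searchsorted(f, targets)
            j = np.clip(j, 0, len(f) - 1)
            ok = f[j] == targets
            i0, i1 = np.nonzero(ok)[0], j[ok]
        if len(i0):
            rs.append(np.hypot(*(xy[i1] - xy[i0]).T))
    r = np.concatenate(rs) if rs else np.array([])
    return pd.DataFrame(
        {"r_um": r, "delay_frames": np.full(len(r), k, int), "tau_s": np.full(len(r), tau)}
    )


@dataclass
class StepHistogram:
    """Binned step-size distribution at a single delay time.

    ``density`` is normalized to unit area over the binned range [0, r_max);
    steps beyond r_max are counted in ``n_overflow`` and excluded.
    """

    tau: float
    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    n_overflow: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.counts = np.asarray(self.counts)
        self.density = np.asarray(self.density, float)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if (np.diff(self.bin_edges) <= 0).any():
            raise ValueError("bin_edges must be increasing")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(np.sum(self.counts))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau_s": self.tau,
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "count": self.counts,
                "density": self.density,
            }
        )


def build_histogram(
    steps: pd.DataFrame | np.ndarray,
    bin_width: float = 0.05,
    r_max: float = 2.5,
    tau: float | None = None,
) -> StepHistogram:
    """Histogram step sizes with uniform bins over [0, r_max).

    ``steps`` is either the table returned by :func:`compute_steps` (all rows
    must share one delay) or a bare array of r values with ``tau`` given
    explicitly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(steps, pd.DataFrame):
        if len(steps) == 0:
            raise ValueError("empty step list")
        taus = steps["tau_s"].unique()
        if len(taus) != 1:
            raise ValueError(f"steps mix several delay times: {sorted(taus)}")
        tau = float(taus[0])
        r = steps["r_um"].to_numpy(float)
    else:
        r = np.asarray(steps, float)
        if r.size == 0:
            raise ValueError("empty step list")
        if tau is None:
            raise ValueError("tau must be given when steps is a bare array")
    n_bins = int(np.ceil(r_max / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(r, bins=edges)
    n_overflow = int(np.sum(r >= edges[-1]))
    if n_overflow:
        logger.info("build_histogram: %d steps beyond r_max=%g excluded", n_overflow, r_max)
    total = counts.sum()
    density = counts / (total * bin_width) if total > 0 else np.zeros(n_bins)
    return StepHistogram(
        tau=tau, bin_edges=edges, counts=counts, density=density, n_overflow=n_overflow
    )
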