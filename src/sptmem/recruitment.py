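"""TIRF recruitment (adsorption) trace processing.

Recruitment of a bulk-phase protein to a supported-lipid bilayer is read out
as the TIRF field intensity over time, sampled every 15 s. The standard
summary is the *difference intensity*: the raw trace minus a baseline equal
to the mean of the four frames immediately preceding ligand addition.
Replicates are aggregated pointwise (mean ± sd across replicates, aligned on
time since addition), and reversibility after a washout step is summarized
as a retained-intensity fraction plus a one-sided monotonic-decay rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AdsorptionTrace

__all__ = [
    "ReplicateSummary",
    "WashoutSummary",
    "difference_intensity",
    "aggregate_replicates",
    "washout_comparison",
    "read_traces",
    "write_traces",
]


def write_traces(traces: Sequence[AdsorptionTrace], path) -> None:
    """Write traces as long-format CSV (time_s, intensity, condition, replicate)."""
    pd.concat([tr.to_frame() for tr in traces], ignore_index=True).to_csv(path, index=False)


def read_traces(path, addition_index: int) -> list[AdsorptionTrace]:
    """Read a long-format trace CSV into one AdsorptionTrace per (condition, replicate)."""
    df = pd.read_csv(path)
    required = {"time_s", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace file needs columns {sorted(required)}")
    if "condition" not in df.columns:
        df["condition"] = ""
    if "replicate" not in df.columns:
        df["replicate"] = 0
    traces = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            AdsorptionTrace(
                times=grp["time_s"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                addition_index=addition_index,
                condition=str(cond),
                replicate=int(rep),
            )
        )
    return traces

BASELINE_FRAMES = 4


def difference_intensity(trace: AdsorptionTrace) -> AdsorptionTrace:
    """Subtract the mean of the four frames preceding addition from the trace."""
    a = trace.addition_index
    if a < BASELINE_FRAMES:
        raise ValueError(
            f"the baseline is defined as the average of the {BASELINE_FRAMES} frames "
            f"preceding addition; addition_index={a} leaves only {a}"
        )
    baseline = float(np.mean(trace.intensities[a - BASELINE_FRAMES : a]))
    return replace(
        trace,
        intensities=trace.intensities - baseline,
        baseline_subtracted=True,
    )


@dataclass
class ReplicateSummary:
    """Pointwise mean ± sd of replicate traces on a common time grid."""

    time_since_addition: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None  # None for a single replicate
    n_replicates: int
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_since_addition_s": self.time_since_addition, "mean_intensity": self.mean}
        )
        if self.sd is not None:
            df["sd_intensity"] = self.sd
        return df


def aggregate_replicates(traces: Sequence[AdsorptionTrace]) -> ReplicateSummary:
    """Pointwise mean and across-replicate standard deviation.

    Traces must share the same grid of time-since-addition values;
    resampling onto a common grid is refused rather than guessed.
    """
    if len(traces) == 0:
        raise ValueError("at least one trace is required")
    ref = traces[0].time_since_addition()
    for tr in traces[1:]:
        t = tr.time_since_addition()
        if t.shape != ref.shape or not np.allclose(t, ref, atol=1e-9):
            raise ValueError(
                "replicate time grids differ (aligned on addition); resampling is "
                "not performed — supply traces on a common grid"
            )
    stack = np.vstack([tr.intensities for tr in traces])
    sd = stack.std(axis=0, ddof=1) if len(traces) > 1 else None
    return ReplicateSummary(
        time_since_addition=ref,
        mean=stack.mean(axis=0),
        sd=sd,
        n_replicates=len(traces),
        condition=traces[0].condition,
    )


@dataclass
class WashoutSummary:
    """Reversibility readout after a buffer / competitor washout."""

    retained_fraction: float
    decay_detected: bool
    p_value: float
    alpha: float = 0.05


def washout_comparison(
    pre: AdsorptionTrace,
    post_wash: AdsorptionTrace,
    alpha: float = 0.05,
    plateau_frames: int = 4,
) -> WashoutSummary:
    """Compare plateau intensity before vs after a washout.

    ``retained_fraction`` is the ratio of the post-wash plateau (mean of the
    final ``plateau_frames`` points) to the pre-wash plateau. Monotonic decay
    in the post-wash segment is tested with a one-sided Kendall rank
    correlation against time (negative trend) at level ``alpha``. Both traces
    must already be baseline-subtracted difference intensities of the same
    sample.
    """
    if len(post_wash.intensities) < 5:
        raise ValueError("post-wash trace must have at least 5 points")
    if not (pre.baseline_subtracted and post_wash.baseline_subtracted):
        raise ValueError("both traces must be baseline-subtracted (difference_intensity)")
    pre_plateau = float(np.mean(pre.intensities[-plateau_frames:]))
    post_plateau = float(np.mean(post_wash.intensities[-plateau_frames:]))
    retained = post_plateau / pre_plateau if pre_plateau != 0 else float("nan")
    seg = post_wash.intensities
    if np.ptp(seg) == 0.0:  # constant segment: no trend by definition
        return WashoutSummary(retained_fraction=retained, decay_detected=False, p_value=1.0,
                              alpha=alpha)
    res = stats.kendalltau(post_wash.times, seg, alternative="less")
    decay = bool(res.pvalue < alpha)
    return WashoutSummary(
        retained_fraction=retained,
        decay_detected=decay,
        p_value=float(res.pvalue),
        alpha=alpha,
    )
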