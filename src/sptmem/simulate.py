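"""Synthetic membrane-diffusion data generator.

Emulates the statistical structure of single-molecule TIRF tracking data on a
supported-lipid bilayer: particles diffuse in 2D with a diffusion coefficient
set by a hidden state, switch states as a continuous-time Markov chain (CTMC),
desorb from the membrane with a state-dependent exponential hazard, and are
recorded at discrete frame ticks with optional localization noise and missed
detections. New particles may adsorb during the movie at a constant rate.

Everything is seeded and byte-for-byte reproducible: one
``numpy.random.Generator`` drives a fixed iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .tracks import TrajectorySet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "AdsorptionTrace",
    "simulate_trajectories",
    "render_detections",
    "simulate_recruitment_trace",
    "ctmc_stationary",
]


def ctmc_stationary(switch_rates: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC given its off-diagonal rate matrix.

    ``switch_rates[i, j]`` is the i→j rate (1/s); diagonal entries are
    ignored. Falls back to the uniform distribution when the chain has no
    transitions (zero matrix), where every distribution is stationary.
    """
    q = np.array(switch_rates, dtype=float)
    k = q.shape[0]
    np.fill_diagonal(q, 0.0)
    if not q.any():
        return np.full(k, 1.0 / k)
    gen = q - np.diag(q.sum(axis=1))  # generator matrix
    # solve pi @ gen = 0, sum(pi) = 1
    a = np.vstack([gen.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic tracking movie.

    Units are µm, seconds and µm²/s throughout. The default immobile state is
    given a small positive D (0.01 µm²/s) rather than exactly zero so that the
    corresponding mixture component remains a proper density.
    """

    n_particles: int = 50
    n_frames: int = 500
    frame_interval: float = 0.02
    fov: tuple[float, float] = (25.0, 25.0)
    #: (label, D in µm²/s) per diffusive state
    states: Sequence[tuple[str, float]] = (("fast", 2.0), ("slow", 0.5), ("immobile", 0.01))
    #: square off-diagonal rate matrix (1/s); zeros = no interconversion
    switch_rates: Sequence[Sequence[float]] | None = None
    #: per-second membrane-desorption rate, scalar or one per state
    desorb_rate_per_state: float | Sequence[float] = 0.0
    #: Poisson rate (1/s) of new particles appearing during the movie
    adsorb_rate: float = 0.0
    loc_noise_sigma: float = 0.0
    p_missed_detection: float = 0.0
    #: "periodic" (default), "reflect", or "none"
    boundary: str = "periodic"
    #: initial hidden-state occupancies; default: CTMC stationary distribution
    initial_state_probs: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.states) < 1:
            raise ValueError("at least one diffusive state is required")
        if any(d < 0 for _, d in self.states):
            raise ValueError("diffusion coefficients must be >= 0")
        k = len(self.states)
        if self.switch_rates is None:
            self.switch_rates = np.zeros((k, k))
        self.switch_rates = np.asarray(self.switch_rates, dtype=float)
        if self.switch_rates.shape != (k, k):
            raise ValueError(f"switch_rates must be a {k}x{k} square matrix")
        off = self.switch_rates[~np.eye(k, dtype=bool)]
        if (off < 0).any():
            raise ValueError("switch rates must be non-negative")
        self.desorb_rate_per_state = np.broadcast_to(
            np.asarray(self.desorb_rate_per_state, dtype=float), (k,)
        ).copy()
        if (self.desorb_rate_per_state < 0).any():
            raise ValueError("desorption rates must be non-negative")
        if not 0.0 <= self.p_missed_detection <= 1.0:
            raise ValueError("p_missed_detection must be in [0, 1]")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be >= 0")
        if self.adsorb_rate < 0:
            raise ValueError("adsorb_rate must be >= 0")
        if self.boundary not in ("periodic", "reflect", "none"):
            raise ValueError("boundary must be 'periodic', 'reflect' or 'none'")
        if self.initial_state_probs is None:
            self.initial_state_probs = ctmc_stationary(self.switch_rates)
        self.initial_state_probs = np.asarray(self.initial_state_probs, dtype=float)
        if self.initial_state_probs.shape != (k,) or not math.isclose(
            self.initial_state_probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("initial_state_probs must be a length-K probability vector")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "states" in raw:
            raw["states"] = [tuple(s) for s in raw["states"]]
        if "fov" in raw:
            raw["fov"] = tuple(raw["fov"])
        if "seed" not in raw:
            raise ValueError("simulation config must specify a seed")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "n_particles": self.n_particles,
            "n_frames": self.n_frames,
            "frame_interval": self.frame_interval,
            "fov": list(self.fov),
            "states": [[lab, float(d)] for lab, d in self.states],
            "switch_rates": np.asarray(self.switch_rates).tolist(),
            "desorb_rate_per_state": np.asarray(self.desorb_rate_per_state).tolist(),
            "adsorb_rate": self.adsorb_rate,
            "loc_noise_sigma": self.loc_noise_sigma,
            "p_missed_detection": self.p_missed_detection,
            "boundary": self.boundary,
            "initial_state_probs": np.asarray(self.initial_state_probs).tolist(),
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """Hidden truth behind a simulated movie, for parameter-recovery tests."""

    #: track_id, frame, x_um, y_um, state (label) — noiseless positions
    data: pd.DataFrame
    #: state label -> true D (µm²/s)
    state_d: dict[str, float]
    #: fraction of recorded frames spent in each state
    occupancies: dict[str, float]
    #: completed membrane dwell times (s); particles alive at movie end excluded
    dwell_times: np.ndarray
    #: number of particles still membrane-bound at the end of the movie
    n_dwell_censored: int


def _state_path(rng, cfg: SimulationConfig, birth: float, t_end: float):
    """Gillespie simulation of the hidden state until desorption or t_end.

    Returns (segment start times, segment states, death time or None).
    """
    k = len(cfg.states)
    q = np.asarray(cfg.switch_rates, float).copy()
    np.fill_diagonal(q, 0.0)
    out_rates = q.sum(axis=1)
    desorb = np.asarray(cfg.desorb_rate_per_state, float)
    s = int(rng.choice(k, p=cfg.initial_state_probs))
    t = birth
    seg_t, seg_s = [t], [s]
    while True:
        total = out_rates[s] + desorb[s]
        if total <= 0:
            return seg_t, seg_s, None
        wait = rng.exponential(1.0 / total)
        t = t + wait
        if t >= t_end:
            return seg_t, seg_s, None
        if rng.random() < desorb[s] / total:
            return seg_t, seg_s, t
        s = int(rng.choice(k, p=q[s] / out_rates[s]))
        seg_t.append(t)
        seg_s.append(s)


def _apply_boundary(pos: np.ndarray, fov: tuple[float, float], mode: str) -> np.ndarray:
    if mode == "none":
        return pos
    size = np.asarray(fov, float)
    if mode == "periodic":
        return np.mod(pos, size)
    # reflect: fold onto a triangle wave of period 2*size
    p = np.mod(pos, 2.0 * size)
    return np.where(p > size, 2.0 * size - p, p)


def simulate_trajectories(config: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate membrane-bound particle trajectories with hidden-state switching.

    Per frame, each particle's position advances by independent Gaussian
    increments with per-axis variance ``2 * D * frame_interval``; when the
    hidden state switches mid-frame the increment variance uses the exact
    time integral of D over the frame, so the discretization is exact at any
    frame interval. Desorption follows a per-state exponential hazard, and —
    when ``adsorb_rate > 0`` — new particles appear as a Poisson process.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval
    t_total = cfg.n_frames * dt
    d_by_state = np.array([d for _, d in cfg.states], float)
    labels = [lab for lab, _ in cfg.states]

    births = [0.0] * cfg.n_particles
    if cfg.adsorb_rate > 0:
        n_new = int(rng.poisson(cfg.adsorb_rate * t_total))
        births.extend(np.sort(rng.uniform(0.0, t_total, size=n_new)).tolist())

    rows_tid: list[np.ndarray] = []
    rows_frame: list[np.ndarray] = []
    rows_xy: list[np.ndarray] = []
    rows_state: list[np.ndarray] = []
    dwell_times: list[float] = []
    n_censored = 0
    tid = 0
    for birth in births:
        seg_t, seg_s, death = _state_path(rng, cfg, birth, t_total)
        if death is None:
            n_censored += 1
            t_end = t_total
        else:
            dwell_times.append(death - birth)
            t_end = death
        # frame ticks falling inside the residence interval [birth, t_end)
        k0 = int(math.ceil(birth / dt - 1e-12))
        k1 = min(cfg.n_frames - 1, int(math.ceil(t_end / dt - 1e-12)) - 1)
        if k1 < k0:
            continue
        frames = np.arange(k0, k1 + 1)
        times = frames * dt
        seg_t_arr = np.asarray(seg_t)
        seg_s_arr = np.asarray(seg_s)
        # integral of D(t): piecewise-linear cumulative with slope D(state)
        knot_t = np.append(seg_t_arr, t_end)
        seg_d = d_by_state[seg_s_arr]
        cum = np.concatenate([[0.0], np.cumsum(seg_d * np.diff(knot_t))])
        cum_at = np.interp(times, knot_t, cum)
        var = 2.0 * np.diff(cum_at)  # per-axis variance of each frame step
        n_pts = len(frames)
        start = rng.uniform([0.0, 0.0], cfg.fov)
        steps = rng.standard_normal((n_pts - 1, 2)) * np.sqrt(var)[:, None]
        pos = start + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        pos = _apply_boundary(pos, cfg.fov, cfg.boundary)
        state_idx = seg_s_arr[np.searchsorted(seg_t_arr, times, side="right") - 1]
        rows_tid.append(np.full(n_pts, tid))
        rows_frame.append(frames)
        rows_xy.append(pos)
        rows_state.append(state_idx)
        tid += 1

    if rows_tid:
        tid_all = np.concatenate(rows_tid)
        frame_all = np.concatenate(rows_frame)
        xy_all = np.concatenate(rows_xy)
        state_all = np.concatenate(rows_state)
    else:
        tid_all = np.array([], int)
        frame_all = np.array([], int)
        xy_all = np.zeros((0, 2))
        state_all = np.array([], int)
    df = pd.DataFrame(
        {
            "track_id": tid_all.astype(int),
            "frame": frame_all.astype(int),
            "x_um": xy_all[:, 0],
            "y_um": xy_all[:, 1],
            "state": [labels[i] for i in state_all],
        }
    )
    occ = (
        df["state"].value_counts(normalize=True).reindex(labels, fill_value=0.0).to_dict()
        if len(df)
        else {lab: 0.0 for lab in labels}
    )
    truth = GroundTruth(
        data=df,
        state_d=dict(zip(labels, d_by_state)),
        occupancies=occ,
        dwell_times=np.asarray(dwell_times),
        n_dwell_censored=n_censored,
    )
    tracks = TrajectorySet(df.drop(columns=["state"]), frame_interval=dt)
    return tracks, truth


def render_detections(
    tracks: TrajectorySet,
    loc_noise_sigma: float = 0.0,
    p_missed_detection: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn trajectories into a per-frame detection table.

    Each localization is perturbed by isotropic Gaussian noise of the stated
    sigma and independently dropped with probability ``p_missed_detection``.
    The originating track id is kept in a hidden ``truth_id`` column so that
    linking can be checked against ground truth.
    """
    if loc_noise_sigma < 0:
        raise ValueError("loc_noise_sigma must be >= 0")
    if not 0.0 <= p_missed_detection <= 1.0:
        raise ValueError("p_missed_detection must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = tracks.data
    n = len(df)
    xy = df[["x_um", "y_um"]].to_numpy(float)
    if loc_noise_sigma > 0:
        xy = xy + rng.normal(0.0, loc_noise_sigma, size=(n, 2))
    keep = rng.random(n) >= p_missed_detection
    out = pd.DataFrame(
        {
            "frame": df["frame"].to_numpy()[keep],
            "x_um": xy[keep, 0],
            "y_um": xy[keep, 1],
            "intensity": np.full(int(keep.sum()), 1000.0),
            "truth_id": df["track_id"].to_numpy()[keep],
        }
    )
    return out.sort_values(["frame", "truth_id"], kind="stable").reset_index(drop=True)


@dataclass
class AdsorptionTrace:
    """A TIRF recruitment (adsorption) intensity time series.

    ``addition_index`` is the index of the first post-addition frame; the
    four frames immediately preceding it define the baseline window.
    """

    times: np.ndarray  # seconds
    intensities: np.ndarray  # arbitrary units
    addition_index: int
    condition: str = ""
    replicate: int = 0
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.addition_index < len(self.times):
            raise ValueError("addition_index out of range")

    def time_since_addition(self) -> np.ndarray:
        return self.times - self.times[self.addition_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "intensity": self.intensities,
                "condition": self.condition,
                "replicate": self.replicate,
            }
        )


def simulate_recruitment_trace(
    baseline_level: float,
    plateau_delta: float,
    rate_per_s: float,
    addition_frame: int,
    frame_interval_s: float = 15.0,
    noise_sigma: float = 0.0,
    n_frames: int = 60,
    seed: int = 0,
    condition: str = "sim",
    replicate: int = 0,
) -> AdsorptionTrace:
    """Simulate a recruitment trace: flat baseline, then exponential approach.

    Frames at index >= ``addition_frame`` read
    ``baseline + plateau_delta * (1 - exp(-rate * t))`` with
    ``t = (frame - addition_frame + 1) * frame_interval_s`` (the intensity is
    recorded at the end of each post-addition interval, so an infinitely fast
    approach steps exactly at ``addition_frame``). Gaussian noise of sd
    ``noise_sigma`` is added everywhere.
    """
    if addition_frame < 5:
        raise ValueError(
            "addition_frame must be >= 5 so that a 4-frame pre-addition baseline exists"
        )
    if rate_per_s < 0:
        raise ValueError("rate_per_s must be >= 0")
    if n_frames <= addition_frame:
        raise ValueError("n_frames must exceed addition_frame")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    times = frames * frame_interval_s
    t_post = (frames - addition_frame + 1.0) * frame_interval_s
    with np.errstate(over="ignore", invalid="ignore"):
        response = plateau_delta * -np.expm1(-rate_per_s * t_post)
    intensity = baseline_level + np.where(frames >= addition_frame, response, 0.0)
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma, size=n_frames)
    return AdsorptionTrace(
        times=times,
        intensities=intensity,
        addition_index=addition_frame,
        condition=condition,
        replicate=replicate,
    )
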