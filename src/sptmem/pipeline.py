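"""End-to-end pipeline: simulate → detect → link → fit, from one YAML config.

Every run writes a machine-readable provenance record (full config, seed,
package version, config hash) beside its outputs, and a manifest naming each
artifact, so any artifact can be regenerated from the record alone. All
randomness derives from the single top-level seed; re-running with the same
config produces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffusion import fit_tracks
from .dwell import compute_dwell_times, dwell_table, fit_dwell
from .recruitment import aggregate_replicates, difference_intensity, write_traces
from .simulate import SimulationConfig, render_detections, simulate_recruitment_trace, simulate_trajectories
from .tracking import filter_tracks, link_detections
from .tracks import TrajectorySet

__all__ = ["ConfigError", "PipelineError", "load_run_config", "run_pipeline", "demo_config_path"]


class ConfigError(ValueError):
    """Raised with a field-by-field list of schema violations."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid run config:\n" + "\n".join(f"  - {p}" for p in problems))


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


_REQUIRED = [
    ("seed", int),
    ("simulation", dict),
    ("simulation.n_particles", int),
    ("simulation.n_frames", int),
    ("simulation.frame_interval", float),
    ("simulation.fov", list),
    ("simulation.states", list),
    ("tracking", dict),
    ("stepsize", dict),
    ("stepsize.delays", list),
    ("dwell", dict),
    ("recruitment", dict),
    ("recruitment.addition_frame", int),
    ("recruitment.n_frames", int),
]


def _get(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            return None
        node = node[part]
    return node


def load_run_config(source: str | Path | dict) -> dict:
    """Load and schema-validate a pipeline config (YAML path or dict)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    problems = []
    for dotted, typ in _REQUIRED:
        val = _get(cfg, dotted)
        if val is None:
            problems.append(f"missing required field: {dotted}")
        elif typ in (int, float) and not isinstance(val, (int, float)):
            problems.append(f"field {dotted} must be numeric, got {type(val).__name__}")
        elif typ in (dict, list) and not isinstance(val, typ):
            problems.append(f"field {dotted} must be a {typ.__name__}")
    if problems:
        raise ConfigError(problems)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_provenance(out_dir: Path, cfg: dict, seed: int) -> Path:
    path = out_dir / "provenance.json"
    _write_json(
        path,
        {
            "config": cfg,
            "seed": seed,
            "package": "sptmem",
            "version": __version__,
            "config_sha256": _config_hash(cfg),
        },
    )
    return path


def demo_config_path() -> Path:
    """Path to the self-contained demo configuration shipped with the package."""
    return Path(resources.files("sptmem") / "data" / "demo_config.yaml")


def run_pipeline(source: str | Path | dict, out_dir: str | Path) -> dict[str, str]:
    """Run every stage in dependency order; returns the artifact manifest.

    Stages: simulate ground-truth trajectories and detections; link
    detections into tracks; step-size extraction and global diffusion
    mixture fit; dwell-time mixture fit; recruitment-trace simulation and
    difference-intensity aggregation. A failing stage aborts with
    :class:`PipelineError` naming the stage.
    """
    cfg = load_run_config(source)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, str] = {}

    def _artifact(name: str, path: Path) -> Path:
        manifest[name] = str(path.relative_to(out))
        return path

    write_provenance(out, cfg, seed)
    manifest["provenance"] = "provenance.json"

    # --- simulate -----------------------------------------------------------
    try:
        sim_cfg = SimulationConfig.from_dict({**cfg["simulation"], "seed": seed})
        tracks_true, truth = simulate_trajectories(sim_cfg)
        truth.data.to_csv(_artifact("truth_tracks", out / "truth_tracks.csv"), index=False)
        detections = render_detections(
            tracks_true,
            loc_noise_sigma=sim_cfg.loc_noise_sigma,
            p_missed_detection=sim_cfg.p_missed_detection,
            seed=seed + 1,
        )
        detections.to_csv(_artifact("detections", out / "detections.csv"), index=False)
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc

    # --- track --------------------------------------------------------------
    try:
        tr_cfg = cfg["tracking"]
        linked = link_detections(
            detections.drop(columns=["truth_id"], errors="ignore"),
            max_link_dist=tr_cfg.get("max_link_dist", 1.5),
            max_gap=tr_cfg.get("max_gap", 2),
            max_gap_dist=tr_cfg.get("max_gap_dist", 1.5),
            frame_interval=sim_cfg.frame_interval,
        )
        linked = filter_tracks(linked, min_length=tr_cfg.get("min_length", 1))
        linked.to_csv(_artifact("tracks", out / "tracks.csv"))
    except Exception as exc:
        raise PipelineError("track", exc) from exc

    # --- step-size diffusion fit -------------------------------------------
    try:
        ss = cfg["stepsize"]
        fit, hists = fit_tracks(
            linked,
            delays=[int(k) for k in ss["delays"]],
            n_components=ss.get("n_components", 3),
            bin_width=ss.get("bin_width", 0.05),
            r_max=ss.get("r_max", 2.5),
            non_overlapping=ss.get("non_overlapping", True),
        )
        pd.concat([h.to_frame() for h in hists], ignore_index=True).to_csv(
            _artifact("histograms", out / "step_histograms.csv"), index=False
        )
        _write_json(_artifact("diffusion_fit", out / "diffusion_fit.json"), fit.to_dict())
        from .plots import plot_step_histograms

        plot_step_histograms(hists, fit, _artifact("stepsize_plot", out / "stepsize_fit.png"))
    except Exception as exc:
        raise PipelineError("stepsize", exc) from exc

    # --- dwell times --------------------------------------------------------
    try:
        samples = compute_dwell_times(linked, movie_n_frames=sim_cfg.n_frames)
        dwell_table(samples).to_csv(_artifact("dwell_times", out / "dwell_times.csv"), index=False)
        dfit = fit_dwell(
            samples,
            n_components=cfg["dwell"].get("n_components", 2),
            frame_interval=sim_cfg.frame_interval,
        )
        _write_json(_artifact("dwell_fit", out / "dwell_fit.json"), dfit.to_dict())
    except Exception as exc:
        raise PipelineError("dwell", exc) from exc

    # --- recruitment --------------------------------------------------------
    try:
        rc = cfg["recruitment"]
        traces = [
            simulate_recruitment_trace(
                baseline_level=rc.get("baseline_level", 100.0),
                plateau_delta=rc.get("plateau_delta", 40.0),
                rate_per_s=rc.get("rate_per_s", 0.02),
                addition_frame=int(rc["addition_frame"]),
                frame_interval_s=rc.get("frame_interval_s", 15.0),
                noise_sigma=rc.get("noise_sigma", 0.0),
                n_frames=int(rc["n_frames"]),
                seed=seed + 100 + i,
                condition="demo",
                replicate=i,
            )
            for i in range(int(rc.get("n_replicates", 3)))
        ]
        diffs = [difference_intensity(tr) for tr in traces]
        write_traces(diffs, _artifact("recruitment_traces", out / "recruitment_traces.csv"))
        summary = aggregate_replicates(diffs)
        summary.to_frame().to_csv(
            _artifact("recruitment_summary", out / "recruitment_summary.csv"), index=False
        )
        from .plots import plot_recruitment

        plot_recruitment(summary, _artifact("recruitment_plot", out / "recruitment.png"))
    except Exception as exc:
        raise PipelineError("recruit", exc) from exc

    _write_json(out / "manifest.json", manifest)
    return manifest
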