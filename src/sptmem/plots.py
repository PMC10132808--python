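"""Plot helpers (matplotlib, Agg backend) for fits and recruitment traces."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diffusion import DiffusionFit, model_density
from .recruitment import ReplicateSummary
from .steps import StepHistogram


def plot_step_histograms(
    histograms: Sequence[StepHistogram], fit: DiffusionFit, path: str | Path
) -> None:
    """Overlay observed step-size densities and the fitted mixture, one panel per delay."""
    n = len(histograms)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), sharey=True, squeeze=False)
    for ax, h in zip(axes[0], histograms):
        ax.bar(h.bin_centers, h.density, width=np.diff(h.bin_edges), alpha=0.5,
               color="steelblue", label="observed")
        r = np.linspace(1e-4, h.bin_edges[-1], 400)
        ax.plot(r, model_density(r, h.tau, fit.components), "k-", lw=1.5, label="fit")
        ax.set_title(f"tau = {h.tau * 1e3:.0f} ms")
        ax.set_xlabel("step size r (um)")
    axes[0][0].set_ylabel("density (1/um)")
    axes[0][0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_recruitment(summary: ReplicateSummary, path: str | Path) -> None:
    """Mean ± sd difference intensity vs time since addition."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    t = summary.time_since_addition
    ax.plot(t, summary.mean, "-", color="firebrick", label="mean")
    if summary.sd is not None:
        ax.fill_between(t, summary.mean - summary.sd, summary.mean + summary.sd,
                        color="firebrick", alpha=0.25, label="± sd")
    ax.axvline(0.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("time since addition (s)")
    ax.set_ylabel("difference intensity (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
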