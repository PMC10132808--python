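"""Multi-component 2D diffusion mixture fit to step-size distributions.

For a molecule undergoing 2D Brownian motion with diffusion coefficient D,
the displacement magnitude r over a delay tau follows the jump-distance
(Rayleigh-form) density

    p(r | D, tau) = (r / (2 D tau)) * exp(-r^2 / (4 D tau)),

with closed-form CDF ``1 - exp(-r^2 / (4 D tau))``. Heterogeneous mobility
(monomer/dimer populations, surface-pinned molecules, condensate-trapped
molecules) produces a K-component mixture with shared weights alpha_i and
coefficients D_i across all delay times; fitting the histograms at several
delays simultaneously ("global fit") pins down the components far better
than any single delay. The mixture density integrates the immobile fraction
as its slowest component, so all components must have D > 0.

The fit minimizes a chi-square between observed histogram densities and the
model's expected per-bin density (exact CDF differences, renormalized over
the binned range to match the histogram normalization). Weighting is
two-stage: a first pass with per-bin weights 1 / max(observed count, 1),
then a refit with the weights frozen at the first-pass model-expected
counts, which removes the few-percent small-sample bias of observed-count
(Neyman) weighting. Optimization is a bounded weighted least-squares over
(log D_i, softmax logits of alpha) from a deterministic grid of
multi-starts, so results are reproducible without any random seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .steps import StepHistogram, build_histogram, compute_steps
from .tracks import TrajectorySet

__all__ = [
    "DiffusionComponent",
    "DiffusionFit",
    "JumpDistanceMixture",
    "model_density",
    "jump_distance_cdf",
    "sample_jump_distances",
    "global_fit",
    "fastest_component",
    "concentration_series",
]


@dataclass(frozen=True)
class DiffusionComponent:
    """One diffusive sub-population: coefficient D (µm²/s) and weight alpha."""

    D: float
    alpha: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if not 0.0 <= self.alpha <= 1.0 + 1e-12:
            raise ValueError("alpha must be in [0, 1]")


def _as_d_alpha(components: Iterable) -> tuple[np.ndarray, np.ndarray]:
    ds, alphas = [], []
    for c in components:
        if isinstance(c, DiffusionComponent):
            ds.append(c.D)
            alphas.append(c.alpha)
        else:
            d, a = c
            ds.append(float(d))
            alphas.append(float(a))
    return np.asarray(ds, float), np.asarray(alphas, float)


def model_density(r, tau: float, components: Sequence) -> np.ndarray:
    """Mixture jump-distance density Σ αᵢ (r / 2Dᵢτ) exp(−r² / 4Dᵢτ)."""
    ds, alphas = _as_d_alpha(components)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if (ds <= 0).any():
        raise ValueError("all component D must be > 0 (degenerate density at D=0)")
    if not np.isclose(alphas.sum(), 1.0, atol=1e-6):
        raise ValueError("component weights must sum to 1")
    r = np.asarray(r, float)
    four_dt = 4.0 * ds * tau
    dens = np.sum(
        alphas * (2.0 * r[..., None] / four_dt) * np.exp(-(r[..., None] ** 2) / four_dt),
        axis=-1,
    )
    return dens


def jump_distance_cdf(r, tau: float, components: Sequence) -> np.ndarray:
    """Mixture CDF Σ αᵢ (1 − exp(−r² / 4Dᵢτ))."""
    ds, alphas = _as_d_alpha(components)
    r = np.asarray(r, float)
    return np.sum(alphas * -np.expm1(-(r[..., None] ** 2) / (4.0 * ds * tau)), axis=-1)


def sample_jump_distances(
    components: Sequence, tau: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n step sizes from the mixture by inverse-CDF sampling.

    Component choice is multinomial in alpha; within a component,
    ``r = sqrt(-4 D tau ln U)`` inverts the single-component CDF exactly.
    """
    ds, alphas = _as_d_alpha(components)
    comp = rng.choice(len(ds), size=n, p=alphas / alphas.sum())
    u = rng.random(n)
    return np.sqrt(-4.0 * ds[comp] * tau * np.log1p(-u))


def expected_bin_density(
    edges: np.ndarray, tau: float, ds: np.ndarray, alphas: np.ndarray
) -> np.ndarray:
    """Model density per bin: exact CDF differences, renormalized over the range."""
    cdf = np.sum(alphas * -np.expm1(-(edges[:, None] ** 2) / (4.0 * ds * tau)), axis=-1)
    p = np.diff(cdf)
    mass = cdf[-1] - cdf[0]
    widths = np.diff(edges)
    return p / (mass * widths)


@dataclass
class DiffusionFit:
    """Result of a global jump-distance mixture fit.

    Components are sorted by descending D; weights sum to 1. Uncertainties
    are standard deviations from the local curvature of the chi-square
    objective at the optimum (see docs/methods.md). Equal-D ties keep the
    deterministic sort order and are flagged in ``tied_components``.
    """

    components: list[DiffusionComponent]
    chi_square: float
    d_uncertainties: np.ndarray
    alpha_uncertainties: np.ndarray
    n_steps_per_delay: dict[float, int]
    delays_used: list[float]
    converged: bool = True
    tied_components: bool = False

    def __post_init__(self) -> None:
        ds = np.array([c.D for c in self.components])
        alphas = np.array([c.alpha for c in self.components])
        if not np.isclose(alphas.sum(), 1.0, atol=1e-6):
            raise ValueError("component weights must sum to 1 within 1e-6")
        if (np.diff(ds) > 1e-12).any():
            raise ValueError("components must be sorted by descending D")
        if (np.asarray(self.d_uncertainties) < 0).any():
            raise ValueError("uncertainties must be >= 0")
        self.tied_components = bool(np.any(np.isclose(np.diff(ds), 0.0)))

    def to_dict(self) -> dict:
        return {
            "components": [{"D_um2_per_s": c.D, "alpha": c.alpha} for c in self.components],
            "d_uncertainties": np.asarray(self.d_uncertainties).tolist(),
            "alpha_uncertainties": np.asarray(self.alpha_uncertainties).tolist(),
            "chi_square": self.chi_square,
            "n_steps_per_delay": {str(k): int(v) for k, v in self.n_steps_per_delay.items()},
            "delays_used": list(self.delays_used),
            "converged": self.converged,
            "tied_components": self.tied_components,
        }


def _unpack(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    ds = np.exp(theta[:k])
    if k == 1:
        return ds, np.ones(1)
    z = np.concatenate([theta[k:], [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return ds, e / e.sum()


class JumpDistanceMixture(BaseEstimator):
    """Global K-component 2D diffusion mixture fit over multiple delay times.

    Scikit-learn style estimator: ``fit`` takes an array of shape (n, 2) with
    columns (r in µm, tau in s) — e.g. ``steps[["r_um", "tau_s"]]`` from
    :func:`sptmem.steps.compute_steps` — bins each delay into a histogram and
    fits one shared set of (D_i, alpha_i) to all of them.

    Parameters
    ----------
    n_components : int
        Number of diffusive components (default 3: fast, intermediate,
        quasi-immobile).
    bin_width, r_max : float
        Histogram binning in µm. The defaults (0.05, 2.5) cover >99.9% of
        the mass for D <= 3 µm²/s and tau <= 0.1 s.
    d_bounds : (float, float)
        Box bounds on each D during optimization, µm²/s.
    n_starts : int
        Number of deterministic multi-starts from log-spaced D grids.

    Attributes
    ----------
    diffusion_coefficients_ : ndarray, descending D per component (µm²/s)
    weights_ : ndarray, mixture weights (sum to 1)
    d_uncertainties_, weight_uncertainties_ : ndarray, curvature-based sds
    chi_square_ : float, final objective value
    fit_result_ : DiffusionFit
    """

    def __init__(
        self,
        n_components: int = 3,
        bin_width: float = 0.05,
        r_max: float = 2.5,
        d_bounds: tuple[float, float] = (1e-4, 50.0),
        n_starts: int = 10,
    ):
        self.n_components = n_components
        self.bin_width = bin_width
        self.r_max = r_max
        self.d_bounds = d_bounds
        self.n_starts = n_starts

    def fit(self, X, y=None) -> "JumpDistanceMixture":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_steps, 2): columns (r_um, tau_s)")
        hists = []
        for tau in np.unique(X[:, 1]):
            r = X[X[:, 1] == tau, 0]
            hists.append(build_histogram(r, self.bin_width, self.r_max, tau=float(tau)))
        self.fit_result_ = self.fit_histograms(hists)
        return self

    def fit_histograms(self, histograms: Sequence[StepHistogram]) -> DiffusionFit:
        """Fit directly from pre-built histograms (one per delay time)."""
        result = _global_fit_core(
            histograms,
            n_components=self.n_components,
            d_bounds=self.d_bounds,
            n_starts=self.n_starts,
        )
        self.fit_result_ = result
        self.diffusion_coefficients_ = np.array([c.D for c in result.components])
        self.weights_ = np.array([c.alpha for c in result.components])
        self.d_uncertainties_ = np.asarray(result.d_uncertainties)
        self.weight_uncertainties_ = np.asarray(result.alpha_uncertainties)
        self.chi_square_ = result.chi_square
        return result

    def predict_density(self, r, tau: float) -> np.ndarray:
        """Fitted mixture density evaluated at r for one delay time."""
        return model_density(r, tau, self.fit_result_.components)


def _global_fit_core(
    histograms: Sequence[StepHistogram],
    n_components: int,
    d_bounds: tuple[float, float],
    n_starts: int,
) -> DiffusionFit:
    if len(histograms) == 0:
        raise ValueError("at least one histogram is required")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    k = int(n_components)
    n_free = 2 * k - 1
    total_steps = sum(h.n_total for h in histograms)
    if total_steps < 10 * n_free:
        raise ValueError(
            f"{total_steps} steps is too few to constrain {n_free} free parameters "
            f"(need >= {10 * n_free})"
        )
    data = [
        (h.tau, h.bin_edges, h.counts.astype(float), h.density) for h in histograms
    ]

    def make_residuals(frozen_w):
        def residuals(theta: np.ndarray) -> np.ndarray:
            ds, alphas = _unpack(theta, k)
            out = []
            for j, (tau, edges, counts, density) in enumerate(data):
                md = expected_bin_density(edges, tau, ds, alphas)
                w = np.maximum(counts, 1.0) if frozen_w is None else frozen_w[j]
                out.append((density - md) / np.sqrt(w))
            return np.concatenate(out)

        return residuals

    residuals = make_residuals(None)

    lo = np.concatenate([np.full(k, np.log(d_bounds[0])), np.full(k - 1, -30.0)])
    hi = np.concatenate([np.full(k, np.log(d_bounds[1])), np.full(k - 1, 30.0)])
    # deterministic multi-start grid: sliding log-spaced D windows
    candidates = np.geomspace(5e-3, 10.0, n_starts + max(k - 1, 0))
    best = None
    any_success = False
    for s in range(n_starts):
        d0 = candidates[s : s + k][::-1]
        x0 = np.concatenate([np.log(d0), np.zeros(k - 1)])
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=5000,
            )
        except Exception:
            continue
        any_success = any_success or res.success
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise RuntimeError("global fit failed to converge from every multi-start")

    # second stage: refit with weights frozen at the stage-1 model-expected
    # counts. With observed counts in the weights (Neyman chi-square), bins
    # that fluctuate low are over-weighted and D is biased a few percent at
    # realistic sample sizes; frozen expected-count weights remove the
    # coupling between weights and residuals.
    ds1, alphas1 = _unpack(best.x, k)
    frozen_w = []
    for tau, edges, counts, _density in data:
        mu = (
            expected_bin_density(edges, tau, ds1, alphas1)
            * np.diff(edges)
            * max(float(counts.sum()), 1.0)
        )
        frozen_w.append(np.maximum(mu, 1.0))
    best = least_squares(
        make_residuals(frozen_w),
        best.x,
        bounds=(lo, hi),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=5000,
    )
    ds, alphas = _unpack(best.x, k)
    chi_square = float(2.0 * best.cost)  # least_squares cost is 0.5 * sum(resid^2)

    d_sd, a_sd = _curvature_uncertainties(best, k, ds, alphas, data, frozen_w)

    order = np.argsort(-ds, kind="stable")
    comps = [DiffusionComponent(float(ds[i]), float(alphas[i])) for i in order]
    # renormalize against softmax round-off so the sum-to-1 invariant is exact
    asum = sum(c.alpha for c in comps)
    comps = [DiffusionComponent(c.D, c.alpha / asum) for c in comps]
    return DiffusionFit(
        components=comps,
        chi_square=chi_square,
        d_uncertainties=d_sd[order],
        alpha_uncertainties=a_sd[order],
        n_steps_per_delay={h.tau: h.n_total for h in histograms},
        delays_used=[h.tau for h in histograms],
        converged=bool(any_success),
    )


def _curvature_uncertainties(res, k, ds, alphas, data, frozen_w):
    """Parameter sds from the curvature at the optimum (sandwich form).

    The objective's per-bin weights are fixed by design (1/max(count, 1) on
    density residuals), so the covariance uses the sandwich estimator
    G (Jᵀ V J) G with G = (JᵀJ)⁻¹ and V the per-residual sampling variance
    from multinomial counting statistics, var(density_i) ≈ μ_i / (N Δr)²
    with μ_i the model-expected count. This stays honest when many tail
    bins are empty, where a pooled residual-variance rescaling would
    dilute the informative bins. Propagated from the internal
    (log D, logits) parameterization to (D, alpha).
    """
    jac = res.jac
    v_parts = []
    for (tau, edges, counts, _density), w in zip(data, frozen_w):
        md = expected_bin_density(edges, tau, ds, alphas)
        widths = np.diff(edges)
        n_steps = max(float(counts.sum()), 1.0)
        p = md * widths  # expected bin probability
        var_dens = p / (n_steps * widths**2)  # var of observed density per bin
        v_parts.append(var_dens / w)  # residuals already carry 1/sqrt(w)
    v = np.concatenate(v_parts)
    g = np.linalg.pinv(jac.T @ jac)
    cov = g @ (jac.T * v) @ jac @ g
    var_logd = np.clip(np.diag(cov)[:k], 0.0, None)
    d_sd = ds * np.sqrt(var_logd)
    if k == 1:
        return d_sd, np.zeros(1)
    cov_z = cov[k:, k:]
    # d alpha_j / d z_l = alpha_j (delta_jl - alpha_l), l = 1..k-1
    a_jac = alphas[:, None] * (np.eye(k)[:, :-1] - alphas[None, :-1])
    var_a = np.clip(np.einsum("jl,lm,jm->j", a_jac, cov_z, a_jac), 0.0, None)
    return d_sd, np.sqrt(var_a)


def global_fit(
    histograms: Sequence[StepHistogram],
    n_components: int = 3,
    d_bounds: tuple[float, float] = (1e-4, 50.0),
    n_starts: int = 10,
) -> DiffusionFit:
    """Fit one shared component set to step-size histograms at all delays."""
    est = JumpDistanceMixture(
        n_components=n_components, d_bounds=d_bounds, n_starts=n_starts
    )
    return est.fit_histograms(histograms)


def fastest_component(fit: DiffusionFit) -> tuple[float, float]:
    """The largest-D component and its fitted standard deviation.

    The fastest coefficient is the reported summary because the slower
    components (intermediate and quasi-immobile) stay consistent across
    conditions while the fast population tracks the monomer/dimer balance.
    """
    if not fit.components:
        raise ValueError("fit has no components")
    return fit.components[0].D, float(np.asarray(fit.d_uncertainties)[0])


def fit_tracks(
    tracks: TrajectorySet,
    delays: Sequence[int] = (1, 2, 3, 4),
    n_components: int = 3,
    bin_width: float = 0.05,
    r_max: float = 2.5,
    non_overlapping: bool = True,
) -> tuple[DiffusionFit, list[StepHistogram]]:
    """Full chain for one condition: steps → histograms → global fit.

    Because the histograms at different delays are built from the *same*
    localizations (a delay-2k step is the sum of two delay-k steps), the
    curvature-based uncertainties — which treat all bins as independent —
    are inflated by sqrt(N_total / N_max): at most ~max_k N_k independent
    displacement observations enter the fit, not the sum over delays.
    """
    hists = []
    for k in delays:
        steps = compute_steps(tracks, k, non_overlapping=non_overlapping)
        hists.append(build_histogram(steps, bin_width=bin_width, r_max=r_max))
    est = JumpDistanceMixture(
        n_components=n_components, bin_width=bin_width, r_max=r_max
    )
    fit = est.fit_histograms(hists)
    counts = np.array([h.n_total for h in hists], float)
    infl = np.sqrt(counts.sum() / counts.max()) if counts.max() > 0 else 1.0
    fit.d_uncertainties = np.asarray(fit.d_uncertainties) * infl
    fit.alpha_uncertainties = np.asarray(fit.alpha_uncertainties) * infl
    return fit, hists


def concentration_series(
    track_sets: Sequence[tuple[str, TrajectorySet]],
    delays: Sequence[int] = (1, 2, 3, 4),
    n_components: int = 3,
    bin_width: float = 0.05,
    r_max: float = 2.5,
    non_overlapping: bool = True,
) -> pd.DataFrame:
    """Fit each labelled condition independently; tidy table of fastest D ± sd.

    Mirrors a titration experiment where the fast-component coefficient is
    compared across solution concentrations or binding-partner conditions.
    """
    if len(track_sets) < 2:
        raise ValueError("a series needs at least two conditions")
    rows = []
    for label, tracks in track_sets:
        fit, _ = fit_tracks(
            tracks,
            delays=delays,
            n_components=n_components,
            bin_width=bin_width,
            r_max=r_max,
            non_overlapping=non_overlapping,
        )
        d_fast, sd = fastest_component(fit)
        rows.append(
            {
                "label": label,
                "d_fast_um2_per_s": d_fast,
                "d_fast_sd": sd,
                "chi_square": fit.chi_square,
                "n_steps": int(sum(fit.n_steps_per_delay.values())),
            }
        )
    return pd.DataFrame(rows)
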