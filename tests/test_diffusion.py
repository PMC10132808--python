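"""Jump-distance mixture model and global fit: normalization, recovery,
scaling law, uncertainty calibration, result invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from sptmem import (
    DiffusionComponent,
    JumpDistanceMixture,
    fastest_component,
    global_fit,
    model_density,
    sample_jump_distances,
)
from sptmem.diffusion import DiffusionFit, expected_bin_density
from sptmem.steps import StepHistogram, build_histogram


def _random_components(rng, k=3):
    ds = rng.uniform(0.01, 3.0, k)
    a = rng.dirichlet(np.ones(k))
    return [(float(d), float(w)) for d, w in zip(ds, a)]


def exact_histogram(components, tau, bin_width=0.05, r_max=2.5, n=100_000):
    """Histogram whose density equals the closed-form expected bin density."""
    edges = np.arange(int(np.ceil(r_max / bin_width)) + 1) * bin_width
    ds = np.array([c[0] for c in components])
    alphas = np.array([c[1] for c in components])
    dens = expected_bin_density(edges, tau, ds, alphas)
    counts = np.maximum(np.round(dens * bin_width * n), 0).astype(int)
    return StepHistogram(tau=tau, bin_edges=edges, counts=counts, density=dens)


class TestModelDensity:
    def test_zero_at_origin(self):
        assert model_density(0.0, 0.02, [(1.0, 1.0)]) == 0.0

    def test_normalization_and_mode_over_random_parameters(self, rng):
        for _ in range(20):
            comps = _random_components(rng)
            integral, _ = quad(lambda r: model_density(r, 0.04, comps), 0, np.inf, limit=200)
            assert integral == pytest.approx(1.0, abs=1e-6)
        # single-component mode at sqrt(2 D tau)
        d, tau = 1.0, 0.02
        r = np.linspace(1e-4, 1.0, 20_000)
        dens = model_density(r, tau, [(d, 1.0)])
        assert r[np.argmax(dens)] == pytest.approx(np.sqrt(2 * d * tau), abs=1e-3)

    def test_rejects_degenerate_and_invalid(self):
        with pytest.raises(ValueError):
            model_density(0.1, 0.02, [(0.0, 1.0)])
        with pytest.raises(ValueError):
            model_density(0.1, 0.02, [(1.0, 0.5)])  # weights don't sum to 1
        with pytest.raises(ValueError):
            model_density(0.1, -0.02, [(1.0, 1.0)])


def test_exact_single_component_recovery():
    h = exact_histogram([(1.3, 1.0)], tau=0.04)
    fit = global_fit([h], n_components=1)
    assert abs(fit.components[0].D - 1.3) / 1.3 < 1e-6


def test_three_component_recovery_from_sampled_steps(rng):
    comps = [(2.0, 0.5), (0.5, 0.3), (0.02, 0.2)]
    hists = [
        build_histogram(sample_jump_distances(comps, k * 0.02, 20_000, rng),
                        bin_width=0.05, r_max=2.5, tau=k * 0.02)
        for k in (1, 2, 3, 4)
    ]
    fit = global_fit(hists, n_components=3)
    for (d_true, a_true), c in zip(comps, fit.components):
        assert abs(c.D - d_true) / d_true < 0.15
        assert abs(c.alpha - a_true) < 0.05


def test_estimator_fit_from_step_array(rng):
    comps = [(1.5, 0.6), (0.05, 0.4)]
    rows = []
    for k in (1, 2):
        tau = k * 0.02
        r = sample_jump_distances(comps, tau, 20_000, rng)
        rows.append(np.column_stack([r, np.full_like(r, tau)]))
    X = np.vstack(rows)
    est = JumpDistanceMixture(n_components=2).fit(X)
    assert est.diffusion_coefficients_[0] == pytest.approx(1.5, rel=0.1)
    assert est.weights_.sum() == pytest.approx(1.0, abs=1e-9)
    # sklearn parameter plumbing
    assert est.get_params()["n_components"] == 2


def test_delay_scaling_law(rng):
    # sampling at delay k*dt is sqrt(k)-scaled delay-dt sampling: the fitted D
    # must not depend on which single delay is used
    fits = []
    for k in (1, 4):
        tau = k * 0.02
        h = build_histogram(sample_jump_distances([(1.0, 1.0)], tau, 100_000, rng),
                            bin_width=0.05, r_max=2.5, tau=tau)
        fits.append(global_fit([h], n_components=1).components[0].D)
    assert fits[0] == pytest.approx(fits[1], rel=0.05)
    assert fits[0] == pytest.approx(1.0, rel=0.05)


def test_fit_invariants_on_sampled_data(rng):
    comps = [(2.0, 0.4), (0.2, 0.6)]
    h = build_histogram(sample_jump_distances(comps, 0.02, 30_000, rng), tau=0.02)
    fit = global_fit([h], n_components=2)
    ds = [c.D for c in fit.components]
    assert ds == sorted(ds, reverse=True)
    assert sum(c.alpha for c in fit.components) == pytest.approx(1.0, abs=1e-6)
    assert np.all(np.asarray(fit.d_uncertainties) >= 0)
    assert fit.chi_square >= 0


class TestFastestComponent:
    def _fit(self, comps):
        return DiffusionFit(
            components=[DiffusionComponent(d, a) for d, a in comps],
            chi_square=0.0,
            d_uncertainties=np.full(len(comps), 0.1),
            alpha_uncertainties=np.zeros(len(comps)),
            n_steps_per_delay={0.02: 1000},
            delays_used=[0.02],
        )

    def test_max_selection(self):
        fit = self._fit([(2.0, 0.5), (0.5, 0.3), (0.02, 0.2)])
        d, sd = fastest_component(fit)
        assert d == 2.0 and sd == 0.1

    def test_single_component(self):
        assert fastest_component(self._fit([(0.7, 1.0)]))[0] == 0.7

    def test_equal_d_tie_documented(self):
        fit = self._fit([(1.0, 0.5), (1.0, 0.5)])
        assert fastest_component(fit)[0] == 1.0
        assert fit.tied_components


def test_errors_for_bad_inputs(rng):
    with pytest.raises(ValueError):
        global_fit([], n_components=1)
    tiny = build_histogram(np.array([0.1, 0.2, 0.3]), tau=0.02)
    with pytest.raises(ValueError, match="too few"):
        global_fit([tiny], n_components=3)


def test_uncertainty_calibration_and_bias(rng):
    # over replicates: relative bias of each D < 5%, and the quoted sd covers
    # the truth at +/- 2 sd in a clear majority of replicates
    comps = [(2.0, 0.5), (0.5, 0.3), (0.02, 0.2)]
    n_rep = 50
    d_fast, sd_fast = [], []
    covered = 0
    for i in range(n_rep):
        r = np.random.default_rng(1000 + i)
        hists = [
            build_histogram(sample_jump_distances(comps, k * 0.02, 5_000, r),
                            bin_width=0.05, r_max=2.5, tau=k * 0.02)
            for k in (1, 2, 3, 4)
        ]
        fit = global_fit(hists, n_components=3)
        d, sd = fastest_component(fit)
        d_fast.append(d)
        sd_fast.append(sd)
        if abs(d - 2.0) <= 2 * sd:
            covered += 1
    assert abs(np.mean(d_fast) - 2.0) / 2.0 < 0.05
    assert covered / n_rep >= 0.7
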