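"""Simulator oracles: closed-form Brownian statistics, CTMC occupancy,
exponential dwell, detection rendering, recruitment traces, determinism."""

import numpy as np
import pytest

from sptmem import (
    SimulationConfig,
    compute_steps,
    ctmc_stationary,
    discrete_exponential_mean,
    render_detections,
    simulate_recruitment_trace,
    simulate_trajectories,
)


def _cfg(**kw):
    base = dict(n_particles=30, n_frames=200, states=[("s", 1.0)], boundary="none", seed=1)
    base.update(kw)
    return SimulationConfig(**base)


def test_zero_diffusion_tracks_are_stationary():
    tracks, _ = simulate_trajectories(_cfg(states=[("pinned", 0.0)], n_particles=5, n_frames=50))
    for _, grp in tracks.itertracks():
        assert np.ptp(grp["x_um"]) == 0.0
        assert np.ptp(grp["y_um"]) == 0.0


def test_msd_matches_2d_brownian_closed_form():
    # E[r^2] per frame = 4 D dt for 2D Brownian motion
    tracks, _ = simulate_trajectories(_cfg(n_particles=60, n_frames=200))
    r2 = compute_steps(tracks, 1, non_overlapping=False)["r_um"].to_numpy() ** 2
    assert len(r2) >= 10_000
    se = r2.std() / np.sqrt(len(r2))
    assert abs(r2.mean() - 4 * 1.0 * 0.02) < 3 * se


@pytest.mark.parametrize("lag", [2, 5])
def test_lagged_steps_scale_linearly_with_delay(lag):
    tracks, _ = simulate_trajectories(_cfg(n_particles=60, n_frames=200, seed=3))
    r2 = compute_steps(tracks, lag, non_overlapping=False)["r_um"].to_numpy() ** 2
    se = r2.std() / np.sqrt(len(r2))
    assert abs(r2.mean() - 4 * 1.0 * lag * 0.02) < 3 * se


def test_symmetric_two_state_occupancy_is_half():
    cfg = _cfg(
        n_particles=20,
        n_frames=3000,
        states=[("a", 1.0), ("b", 0.1)],
        switch_rates=[[0.0, 2.0], [2.0, 0.0]],
        seed=2,
    )
    _, truth = simulate_trajectories(cfg)
    n = len(truth.data)
    # binomial sampling error on correlated frames; use a generous 5/sqrt(n_eff)
    # with n_eff ~ n * (switch rate * dt) independent sojourns
    n_eff = n * 2.0 * 0.02
    assert abs(truth.occupancies["a"] - 0.5) < 5 / np.sqrt(n_eff)


def test_ctmc_stationary_matches_rate_ratio():
    pi = ctmc_stationary(np.array([[0.0, 1.0], [3.0, 0.0]]))
    assert pi == pytest.approx([0.75, 0.25])


def test_true_dwell_times_mean_one_over_lambda():
    lam = 2.0
    cfg = _cfg(n_particles=3000, n_frames=1500, desorb_rate_per_state=lam, seed=4)
    _, truth = simulate_trajectories(cfg)
    d = truth.dwell_times
    se = d.std() / np.sqrt(len(d))
    assert abs(d.mean() - 1 / lam) < 3 * se


def test_observed_durations_match_discrete_geometric_correction():
    # (last - first + 1) * dt is dt * Geometric(1 - e^{-lambda dt}); the
    # corrected estimator recovers 1/lambda where the naive mean is biased high
    lam, dt = 2.0, 0.02
    rng = np.random.default_rng(8)
    q = np.exp(-lam * dt)
    dur = dt * rng.geometric(1 - q, size=200_000)
    est = discrete_exponential_mean(dur, dt)
    se = dur.std() / np.sqrt(dur.size)
    assert abs(est - 1 / lam) < 3 * se
    assert dur.mean() - 1 / lam > 3 * se  # naive mean really is biased


def test_simulation_is_bitwise_deterministic():
    cfg = dict(n_particles=10, n_frames=50, states=[("a", 1.0), ("b", 0.1)],
               switch_rates=[[0, 1], [1, 0]], desorb_rate_per_state=0.5,
               adsorb_rate=5.0, seed=11)
    t1, g1 = simulate_trajectories(SimulationConfig(**cfg))
    t2, g2 = simulate_trajectories(SimulationConfig(**cfg))
    assert t1.data.equals(t2.data)
    assert g1.data.equals(g2.data)
    d1 = render_detections(t1, 0.02, 0.1, seed=3)
    d2 = render_detections(t2, 0.02, 0.1, seed=3)
    assert d1.equals(d2)


def test_boundary_modes_keep_positions_in_fov():
    for mode in ("periodic", "reflect"):
        tracks, _ = simulate_trajectories(
            _cfg(boundary=mode, fov=(5.0, 5.0), n_particles=10, n_frames=300, seed=6)
        )
        xy = tracks.data[["x_um", "y_um"]].to_numpy()
        assert xy.min() >= 0.0 and xy.max() <= 5.0


class TestRenderDetections:
    def test_noiseless_identity(self):
        tracks, _ = simulate_trajectories(_cfg(n_particles=5, n_frames=20))
        det = render_detections(tracks, 0.0, 0.0, seed=1)
        assert len(det) == len(tracks.data)
        merged = det.merge(tracks.data, left_on=["truth_id", "frame"],
                           right_on=["track_id", "frame"])
        assert np.allclose(merged["x_um_x"], merged["x_um_y"])

    def test_all_missed_gives_empty_table(self):
        tracks, _ = simulate_trajectories(_cfg(n_particles=5, n_frames=20))
        det = render_detections(tracks, 0.0, 1.0, seed=1)
        assert len(det) == 0

    def test_noise_variance_is_two_sigma_squared(self):
        tracks, _ = simulate_trajectories(_cfg(n_particles=60, n_frames=200))
        sigma = 0.02
        det = render_detections(tracks, sigma, 0.0, seed=2)
        merged = det.merge(tracks.data, left_on=["truth_id", "frame"],
                           right_on=["track_id", "frame"])
        dev2 = ((merged["x_um_x"] - merged["x_um_y"]) ** 2
                + (merged["y_um_x"] - merged["y_um_y"]) ** 2).to_numpy()
        assert len(dev2) >= 10_000
        se = dev2.std() / np.sqrt(len(dev2))
        assert abs(dev2.mean() - 2 * sigma**2) < 3 * se

    def test_rejects_bad_probability(self):
        tracks, _ = simulate_trajectories(_cfg(n_particles=2, n_frames=5))
        with pytest.raises(ValueError):
            render_detections(tracks, 0.0, 1.5, seed=0)


class TestRecruitmentTrace:
    def test_zero_plateau_is_flat(self):
        tr = simulate_recruitment_trace(100.0, 0.0, 0.1, 8, noise_sigma=0.0, n_frames=30, seed=0)
        assert np.allclose(tr.intensities, 100.0)

    def test_infinite_rate_is_step_function(self):
        tr = simulate_recruitment_trace(10.0, 5.0, np.inf, 8, noise_sigma=0.0, n_frames=30, seed=0)
        assert np.allclose(tr.intensities[:8], 10.0)
        assert np.allclose(tr.intensities[8:], 15.0)

    def test_noiseless_trace_matches_closed_form(self):
        base, delta, rate, a, dt = 50.0, 20.0, 0.03, 6, 15.0
        tr = simulate_recruitment_trace(base, delta, rate, a, frame_interval_s=dt,
                                        noise_sigma=0.0, n_frames=40, seed=0)
        k = np.arange(40)
        t = (k - a + 1) * dt
        expected = np.where(k >= a, base + delta * (1 - np.exp(-rate * t)), base)
        np.testing.assert_allclose(tr.intensities, expected, rtol=1e-12)

    def test_rejects_too_early_addition(self):
        with pytest.raises(ValueError, match="baseline"):
            simulate_recruitment_trace(1.0, 1.0, 0.1, addition_frame=3, n_frames=20)


@pytest.mark.parametrize(
    "kw",
    [
        dict(n_frames=0),
        dict(frame_interval=0.0),
        dict(states=[("s", -1.0)]),
        dict(switch_rates=[[0.0, 1.0]]),  # non-square
        dict(switch_rates=[[0.0, -1.0], [1.0, 0.0]]),
        dict(p_missed_detection=1.2),
        dict(desorb_rate_per_state=-0.5),
        dict(boundary="bounce"),
    ],
)
def test_config_invariants_rejected(kw):
    base = dict(n_particles=5, n_frames=10, states=[("s", 1.0)], seed=0)
    if "states" in kw or "switch_rates" in kw:
        base["states"] = [("a", 1.0), ("b", 0.5)]
    base.update(kw)
    with pytest.raises(ValueError):
        SimulationConfig(**base)
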