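# sptmem

Single-particle tracking analysis of membrane-bound proteins on
supported-lipid bilayers: trajectory simulation, detection linking,
jump-distance (step-size) diffusion analysis, membrane dwell times, and
TIRF recruitment traces.

## The problem

In single-molecule TIRF experiments, a fluorescently labelled protein (for
example a kinase recruited to PIP₃ lipids) is tracked as it diffuses on a
planar bilayer. Two readouts carry the biophysics:

- **Mobility.** 2D diffusion on a membrane slows measurably when molecules
  dimerize or get trapped in protein condensates, so the diffusion
  coefficient of the fast population is a sensitive dimerization probe.
- **Membrane residence.** The dwell time of single molecules reflects the
  membrane off-rate; a binding partner that stabilizes membrane engagement
  shows up as longer dwell times.

This package implements the full desk-side analysis for such experiments,
plus a ground-truth simulator so every stage is testable without any raw
movie data.

## The model

For 2D Brownian motion with diffusion coefficient *D*, the displacement
magnitude *r* over a delay *τ* follows the jump-distance density

```
ρ(r, τ) = Σᵢ αᵢ · r / (2 Dᵢ τ) · exp(−r² / (4 Dᵢ τ)),     Σᵢ αᵢ = 1
```

A heterogeneous population (monomer, dimer, surface-pinned) needs two to
three components. Step-size histograms are built at several delay times
(20–80 ms by default, i.e. every 1–4 frames at 20 ms exposure; a 2–5 frame
variant is available) using non-overlapping frame pairs to avoid
over-counting, and a **global fit** shares one set of (Dᵢ, αᵢ) across all
delays. The fastest component is the reported summary; its uncertainty is
the standard deviation from the curvature of the fit.

Dwell times — `(last frame − first frame + 1) × Δt` per track, with
movie-boundary tracks censored — are fit with a two-component exponential
mixture by EM. Recruitment traces are summarized as *difference intensity*:
raw TIRF intensity minus the mean of the four frames preceding ligand
addition.

Tracking follows the standard linear-assignment rules (linking distance
1.5 µm, frame gap ≤ 2, gap distance 1.5 µm), solved exactly with the
Hungarian algorithm, with a gap-closing second pass.

## Worked example

The packaged demo simulates a three-state movie (D = 2.0, 0.5, 0.01 µm²/s),
renders noisy detections, links them, and runs every analysis stage:

```bash
sptmem pipeline --out demo_out
```

`demo_out/diffusion_fit.json` then contains the fitted mixture (numbers
from the shipped seed):

```
D = 2.031 +/- 0.095 um2/s  alpha = 0.227
D = 0.491 +/- 0.026 um2/s  alpha = 0.373
D = 0.014 +/- 0.000 um2/s  alpha = 0.400
```

The fast and intermediate coefficients recover the simulated truth; the
quasi-immobile component reads 0.014 rather than 0.010 µm²/s because
localization noise (σ = 15 nm in the demo) inflates an apparent D by
≈ σ²/τ — the model deliberately contains no noise term, matching how such
fits are done in practice (see `docs/methods.md`). The dwell fit in
`dwell_fit.json` and the recruitment summary in `recruitment_summary.csv`
come from the same seeded run; dwell means on this short (8 s) demo movie
are biased low because long-lived tracks hit the movie end and are
censored.

Individual stages are available as subcommands (`sptmem simulate`,
`track`, `stepsize`, `dwell`, `recruit`, `validate-tracks`) and as library
functions (`sptmem.JumpDistanceMixture`, `sptmem.DwellTimeMixture`,
`sptmem.link_detections`, ...). Tracks exported by TrackMate can be
imported directly (`sptmem track --trackmate --pixel-size-um ...`).

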