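# Methods

This note documents the models, estimators, numerical choices and known
limitations of `sptmem`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Jump-distance mixture model

For free 2D Brownian motion with diffusion coefficient `D`, the
displacement magnitude `r` over a delay `τ` has density
`p(r) = (r / 2Dτ) · exp(−r² / 4Dτ)` and CDF `1 − exp(−r² / 4Dτ)`.
Mobility heterogeneity is modelled as a K-component mixture with weights
`αᵢ` and coefficients `Dᵢ` shared across all delay times (default K = 3:
fast, intermediate, quasi-immobile). Per-delay weights are deliberately
not allowed: one population structure must explain every delay, which is
what makes the global fit identifying.

**Step extraction.** A step at delay k frames joins two localizations of
one track exactly k frames apart. The default non-overlapping mode pairs
frames (f₀, f₀+k), (f₀+k, f₀+2k), … anchored at the track's first frame,
giving `floor((L−1)/k)` steps for a gap-free L-point track; overlapping
(sliding-window) extraction is available but over-counts correlated
displacements. Gap-closed tracks contribute a step only when both
endpoint frames exist at the exact spacing.

**Binning.** Uniform bins of 0.05 µm over [0, 2.5 µm); this covers
> 99.9 % of the mass for D ≤ 3 µm²/s and τ ≤ 0.1 s. Overflow steps (e.g.
artifacts from periodic-boundary wraps in simulations) are counted,
logged and excluded; densities are normalized to unit area over the
binned range.

**Expected bin density.** The model's per-bin density is the exact CDF
difference divided by the bin width, renormalized over the binned range
so that model and histogram share the same normalization convention.
This is exact at any bin width (a midpoint-rule approximation would
leave O(Δr²) discretization bias) and is what makes noiseless
single-component recovery exact to optimizer tolerance.

**Objective and weighting.** The fit minimizes
`χ² = Σ_delays Σ_bins w_b (density_obs − density_model)²` in two stages:
stage 1 uses `w_b = 1 / max(observed count, 1)`; stage 2 refits from the
stage-1 optimum with weights frozen at the stage-1 *model-expected*
counts. Observed-count (Neyman) weighting alone over-weights bins that
fluctuate low and biases the fast coefficient by a few percent at
realistic sample sizes; freezing the weights at expected counts removes
the coupling between weights and residuals while keeping the simple
chi-square form. Up to a per-histogram constant, inverse-count weights
are the correct inverse-variance weights for multinomial histogram
densities.

**Optimization.** Bounded weighted least squares
(`scipy.optimize.least_squares`, trust-region reflective) over
`(ln Dᵢ, softmax logits of α)` with D ∈ [1e−4, 50] µm²/s, from 10
deterministic multi-starts on a sliding log-spaced D grid; the best final
cost wins, ties by first start. No randomness enters the fit, so results
are bit-reproducible. Equal-D ties in the descending sort keep the
deterministic order and set a `tied_components` flag.

**Uncertainties.** Reported per-component standard deviations come from
the curvature at the optimum in sandwich form,
`G (Jᵀ V J) G` with `G = (JᵀJ)⁻¹` and `V` the per-bin sampling variance
`μ_b / (N Δr)²` (μ_b = model-expected count), propagated from the
internal parameterization to (D, α). A pooled residual-variance rescaling
was rejected because the many empty tail bins dilute it and produce
under-coverage. For fits on track data at multiple delays, the quoted
uncertainties are additionally inflated by `sqrt(N_total / N_max)`:
delay-2k steps are sums of delay-k steps, so at most ~max_k N_k
independent displacement observations enter the fit, not the sum over
delays. Coverage of the quoted sd is checked by replicate simulation in
the test suite.

**Delay sets.** Default delays are 1–4 frames (20–80 ms at 20 ms
exposure); a 2–5 frame variant is selectable. Both conventions appear in
practice and neither is treated as canonical.

**Localization noise.** The density contains no noise term; a static
localization error σ inflates an apparent coefficient by ≈ σ²/τ (e.g.
15 nm noise at τ = 20 ms adds ≈ 0.011 µm²/s). This matters only for the
quasi-immobile component at short delays and is left uncorrected by
design — the model mirrors standard practice; the caveat is documented
instead. For the same reason the immobile population is simulated with a
small positive D (default 0.01 µm²/s), since a zero-D component makes
the mixture density degenerate at r = 0.

## Dwell-time analysis

A track spanning frames f₀..f₁ contributes a duration
`(f₁ − f₀ + 1) · Δt`; tracks touching frame 0 or the last movie frame
are censored and excluded from fitting (their count is reported).
Uncensored durations are fit with a K-component exponential mixture
(default K = 2) by EM from 5 deterministic quantile-split
initializations; the best final likelihood wins and is verified to
dominate every initialization. Sub-frame visits are unobservable, so
track-derived durations are left-truncated at one frame interval: the
component densities are renormalized on [Δt, ∞) and fitted fractions are
mapped back to the untruncated population via `πⱼ ∝ π̂ⱼ · exp(Δt/μⱼ)`.
Component means are floored at Δt/2 (sub-frame structure is not
resolvable), which also prevents the classic likelihood divergence on
the spike of single-frame durations. A survival-curve least-squares mode
(`fit_dwell_survival`) is provided as a cross-check; MLE is the default
for efficiency.

**Discretization.** A molecule resident for an Exp(λ) time is observed
in a geometric number of frame ticks: with `q = exp(−λΔt)` the observed
duration is `Δt · Geometric(1−q)`, whose mean `Δt/(1−q)` exceeds `1/λ`
by ≈ λΔt/2. `discrete_exponential_mean` inverts the geometric mean
exactly and is the estimator used in the single-rate oracle tests, where
the naive mean demonstrably fails a 3-SE check that the corrected
estimator passes.

**Caveats.** Censored-track exclusion biases fitted means low when the
movie is not much longer than the true dwell (the oracle tests use
movies ≥ 200 × 1/λ so this truncation is below the sampling noise).
Photobleaching is not corrected, so fitted off-rates are apparent rates.

## Tracking

Frame-to-frame linking is a one-to-one assignment minimizing total
squared displacement among pairs within the linking gate (default
1.5 µm), solved exactly via the Hungarian algorithm on the standard
augmented cost matrix (no-link entries priced at gate²/2 so every
within-gate link is preferred over leaving both endpoints unlinked).
Gap closing is a second matching pass joining terminated track ends to
tracks starting 2..max_gap+1 frames later within the gap gate (default
2 frames, 1.5 µm), shortest gap first. Exact recovery of ground-truth
partitions is expected — and tested — only in the sparse noiseless
regime (≲ 0.05 particles/µm²); at higher densities occasional
close-encounter ambiguities are unavoidable for any tracker. No track
splitting/merging and no drift correction are implemented. Spot
detection from images is out of scope; the pipeline starts from
detection tables (or TrackMate track exports, with µm-per-pixel
conversion at import).

## Synthetic data generator

The simulator emulates the assumed statistical structure of
single-molecule TIRF movies: hidden diffusive states switching as a
continuous-time Markov chain (simulated by exact exponential waiting
times, not a per-frame Bernoulli approximation — when a switch falls
inside a frame, the increment variance uses the exact time integral of
D over the frame); per-state exponential desorption; optional Poisson
adsorption of new particles; uniform initial positions in a finite
field of view with periodic (default), reflecting, or unbounded
boundaries; isotropic Gaussian localization noise; and independent
missed detections. One `numpy.random.Generator` with a fixed iteration
order makes outputs byte-identical per seed. Default study conditions
follow the three-state structure used throughout the tests (fast
≈ 2 µm²/s, intermediate ≈ 0.5 µm²/s, quasi-immobile, 20 ms frames).
Initial state occupancies default to the switching-matrix stationary
distribution and are settable directly (needed when states do not
interconvert, where every distribution is stationary).

Not emulated: photophysics beyond missed detections (no blinking
kinetics, no bleaching lifetime), spot shape / camera images (simulation
stops at detection tables), anomalous diffusion, and spatially varying
membranes. Passing parameter-recovery tests therefore demonstrates
correctness of the estimators under the stated generative assumptions,
not robustness to bleaching or anomalous transport in real movies.

## Recruitment traces

Difference intensity subtracts the mean of the four frames immediately
preceding addition; the subtraction is additive (not ratio
normalization), so the baseline window of any difference trace averages
to zero by construction. Replicates must share a time grid aligned on
addition (resampling is refused, not guessed); aggregation reports
pointwise mean and across-replicate sd. Washout reversibility reports
the post/pre plateau ratio (mean of the final four frames each) and a
monotonic-decay flag from a one-sided Kendall rank test at level 0.05 —
a deliberate operationalization of an otherwise qualitative judgement.
No kinetic (kon/koff) fitting is performed.

## Problem sizes

Test and acceptance runs use simulation scales chosen to keep Monte-Carlo
error well below the assertion tolerances: ≥ 10⁴ steps for closed-form
MSD/noise checks, 2 × 10⁵ inverse-CDF samples for three-component
recovery (each D within 15 %, each α within 0.05), 2 × 10⁴ draws for
dwell-mixture recovery, ~5 × 10⁴ tracked steps per condition for the
concentration-series trend, and 5 seeded movies for exact tracker
recovery. The homogeneity of a matched null series is tested with the
standard chi-square test at the 1 % level on the fitted fast
coefficients and their quoted uncertainties.
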