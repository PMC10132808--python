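# Self-contained demo: simulates a three-state membrane-diffusion movie,
# links the rendered detections, fits the diffusion mixture and dwell times,
# and processes synthetic recruitment traces. All randomness comes from the
# single seed below.
seed: 7
simulation:
  n_particles: 40
  n_frames: 400
  frame_interval: 0.02
  fov: [30.0, 30.0]
  states:
    - [fast, 2.0]
    - [intermediate, 0.5]
    - [immobile, 0.01]
  initial_state_probs: [0.5, 0.3, 0.2]
  desorb_rate_per_state: [2.0, 0.5, 0.5]
  adsorb_rate: 40.0
  loc_noise_sigma: 0.015
  p_missed_detection: 0.02
  boundary: periodic
tracking:
  max_link_dist: 1.5
  max_gap: 2
  max_gap_dist: 1.5
  min_length: 1
stepsize:
  delays: [1, 2, 3, 4]
  n_components: 3
  bin_width: 0.05
  r_max: 2.5
  non_overlapping: true
dwell:
  n_components: 2
recruitment:
  baseline_level: 100.0
  plateau_delta: 40.0
  rate_per_s: 0.02
  addition_frame: 8
  frame_interval_s: 15.0
  noise_sigma: 1.0
  n_frames: 60
  n_replicates: 3
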