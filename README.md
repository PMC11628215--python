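# reach-ofc

Optimal-feedback-control modelling and analysis of multisensory reaching
corrections.

When a reaching arm is pushed sideways by a load while the displayed hand
cursor is simultaneously shifted, the corrective response blends
proprioceptive and visual information. Two separable computations shape that
blend: a state estimator (Kalman filter) that weighs the visual feedback by
its reliability and accumulates it over time, and a control policy whose
gains grow with urgency, i.e. with less remaining movement time. This
package implements both halves at desk scale for researchers in
computational sensorimotor control:

* an LQG simulator of a planar point-mass reach (mass 1 kg, damping
  0.1 N·s/m, first-order muscle filter τ = 66 ms, Euler step 10 ms) with a
  9 N lateral load triggered at 0.5 cm and a ±2 cm cursor jump at 8 cm of
  forward travel, under four visual-uncertainty levels and two movement
  times (400/700 ms + 500 ms stabilization);
* the full behavioral analysis pipeline for long-format trial tables:
  dual-pass Butterworth filtering, shift-slope regression, dispersion
  ellipses, lateral-force and EMG contrasts, running-t onset estimation
  with participant bootstrap, and repeated-measures/mixed ANOVA with
  partial η²;
* a synthetic-experiment generator that reproduces the published
  two-session design (768 trials per participant) with known ground-truth
  visual weights, so every analysis stage is testable end to end.

## Model

State per axis `x = [p, ṗ, F_com, F_ext, p_c, p_off]ᵀ` plus a constant
target state; the cursor follows the hand plus an unobservable offset
(`p_c,t+1 = p_t+1 + p_off,t`). Discrete dynamics `x_{t+1} = A x_t + B u_t + ξ_t`,
observations `y_t = H x_t + ω_t` with `H = diag(1,1,1,1,1,0)` over the base
states. Control gains come from the backward Riccati recursion for
`J = Σ xᵀQx + uᵀRu` with `R = 10⁻⁴` and Q penalizing the cursor–target error
only during the final 500 ms; Kalman gains from the estimator Riccati
equation run at its stationary point, with small pseudo process noise on
`F_ext` (1% of the motor variance) and `p_off` (0.1%) so step perturbations
remain estimable. Visual uncertainty scales the cursor-channel observation
variance by {0.1, 1, 10, ∞}. The central readout is the *shift slope* —
lateral hand position regressed on jump size; 0 means vision ignored, −1
full compensation.

## Worked example

```bash
python analysis/01_simulate_model.py      # 600 simulated trials
python analysis/02_model_readouts.py
```

prints, with the default configuration and seed 0:

```
fast/low slope at 400 ms: -1.011 (full compensation = -1)
convergence (low): fast 350 ms, slow 420 ms -> lag 70 ms
error half-times fast (low/med/high): 50/160/470 ms
error half-times slow (low/med/high): 50/160/460 ms
```

Read: in the fast, low-uncertainty condition the simulated correction fully
compensates the cursor jump by ~350 ms, and the slow condition needs ~70 ms
longer — an urgency effect carried entirely by the control gains, because
the estimation-error half-times (50/160/470 ms for increasing visual
uncertainty) are the same at both speeds. `03_generate_synthetic_experiment.py`,
`04_behavior_pipeline.py` and `05_statistics.py` continue the chain: the
pipeline recovers the generator's visual weights (e.g. fast/low slope
−0.725 ± 0.013 against a ground truth of −0.750 at 4 participants) and the
injected 100 ms EMG response latency to within a few milliseconds.

A `reach-ofc` command exposes the same steps
(`simulate`, `figures`, `synth`, `analyze`) for use from a shell.

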