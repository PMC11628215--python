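# Methods

## Plant and control model

The arm is a planar point mass (m = 1 kg) with viscous damping
(G = 0.1 N·s/m); the commanded force passes through a first-order muscle
filter with time constant τ = 66 ms. Euler discretization at δt = 10 ms
gives, per axis, the state `[p, ṗ, F_com, F_ext, p_c, p_off]` plus one
constant target state; the two axes are independent (block-diagonal
system). The displayed cursor tracks the hand plus a held offset,
`p_c,t+1 = p_t+1 + p_off,t`; the offset is the one state the observation
matrix excludes, so a cursor jump must be inferred from cursor-position
innovations.

Perturbations are scripted on the true state: the external force steps to
9 N rightward at the first sample with y > 0.5 cm and stays on; the offset
steps to ±2 cm at the first sample with y ≥ 8 cm. Trials last the movement
time (400 or 700 ms) plus a 500 ms stabilization phase.

The control penalty is R = 10⁻⁴ per control channel throughout. The state
cost is zero during the movement and penalizes the squared cursor−target
error during stabilization with weight `q_pos = 10` per axis. `q_pos` was
chosen so the noise-free endpoint error is well under 1 mm (it is ~0.01 mm)
and — a useful byproduct — peak forward velocities are 0.67/0.41 m/s for
the fast/slow horizons, matching typical human values for this task. A
velocity weight exists in the config but defaults to 0 (the cost penalizes
position only). Because the cost sits at the end of the horizon, the
backward Riccati recursion produces control gains that, at a given distance
from the target, are larger when less time remains: the urgency mechanism
that makes fast movements respond more vigorously to the same estimated
error.

## Estimator

The filter is the standard predict/correct cycle
`x̂p = A x̂ + B u`, `x̂⁺ = x̂p + K (y − H x̂p)`, with the innovation taken at
the same time index as the prediction. Because `F_ext` and `p_off` are
physically noiseless but step-perturbed, the Kalman-gain computation (and
only it) injects pseudo process noise on those states: 1% of the motor
variance on `F_ext` and 0.1% on `p_off`. Forward simulations never draw
from the pseudo terms.

For the additive-noise model the recursion is initialized at the fixed
point of the estimator Riccati map (computed with
`scipy.linalg.solve_discrete_are`, with a fixed-point iteration fallback),
so the gain schedule is constant in time. This is a deliberate design
choice: it makes the estimation dynamics — and therefore the jump-aligned
error decay — exactly independent of the movement horizon, which is the
property the model analysis turns on. A transient-phase filter started from
an arbitrary covariance would break that identity merely because the jump
occurs at different absolute steps in the 400 and 700 ms horizons. The
forward recursion itself is retained and drives the signal-dependent-noise
variant, where per-step covariances evaluated along the nominal noise-free
trajectory produce genuinely time-varying gains (a full noise-dependent
optimal control solution would need an iterative solver; the
nominal-trajectory approximation keeps the standard recursions).

The no-vision condition is implemented as an exact infinite-variance limit:
the cursor-innovation columns of K and the `p_off` gain row (whose error is
then uncoupled from every observed channel) are identically zero. A large
finite variance is used only inside the Riccati solve for well-posedness.
This makes the no-vision predictions exact — zero jump-direction
separation, zero force contrast — rather than leaking ~10⁻⁴-scale gains.

## Noise calibration

The magnitudes of Σ_m and Σ_ω are calibration constants, not measurements.
Two facts structure the choice. First, the Kalman gains depend only on
noise *ratios* (they are invariant to a joint rescaling of all SDs;
verified numerically to ~10⁻¹²). The ratios were set so that the fast,
low-uncertainty shift slope converges near −1 within ~300–400 ms of the
jump, the model's published behavior-matching criterion. Second, the free
overall scale fixes only the Monte-Carlo spread of simulated ensembles; it
was set small (motor SD 0.01 N per step; sensory SDs 0.5 mm position,
5 mm/s velocity, 0.05/0.02 N forces, 7 mm baseline cursor) so that
25-run ensemble readouts carry negligible sampling error, as in the
published simulated traces. With a 10× larger scale the convergence-time
statistic at 25 runs has ±200 ms estimator noise — a random-walk wander of
integrated position noise that no pointwise smoothing removes — which would
swamp the ~100 ms speed effect it is meant to measure. All values live in
`src/reach_ofc/configs/default.yaml`.

## Model readouts

Slopes are computed on jump-aligned ensemble means: each run is aligned at
its own 8 cm crossing, the three jump levels (−2, 0, +2 cm) are averaged
per cell, and the lateral position is regressed on jump size through the
same least-squares code path the behavioral pipeline uses. Convergence time
is the first time the slope curve is within 0.05 of its asymptote with no
later excursion, where the asymptote is the mean over the trailing 100 ms
and the rule is applied after an 11-sample centered moving average (the
same window used to display group traces); the raw rule is available via
`smooth_window=1`. The estimation-error decay readout runs on probe
ensembles *without* the load: with the load on, filter cross-covariances
leak a millimeter-scale transient into the offset estimate whose phase
differs between horizons, contaminating a curve that is otherwise
horizon-identical to <10⁻¹⁶ (and the published decay figures likewise start
exactly at the jump size). The peak force-contrast comparison between
speeds is evaluated on noise-free traces: at high uncertainty the true gap
(~0.04 N) is smaller than the max-of-noisy-trace bias at 25 runs.

## Behavioral pipeline

Positions are filtered with a dual-pass (zero-phase) 4th-order Butterworth
low-pass at 50 Hz; velocities are 4th-order central differences of the raw
positions (exact through quartics in the interior; one-sided second-order
stencils at the edges) passed through the same filter. EMG is bandpass
filtered ([20, 250] Hz, 8th-order dual-pass, second-order sections),
rectified, and normalized by the mean rectified activity in a 1 s window
starting 0.5 s after the calibration-force onset, per muscle and speed
session. Filtering uses reflect padding with pad lengths several times the
filter order. Vision onset is the first sample with y ≥ 8 cm; the offset
follows from the experiment/speed-specific viewing duration (100 ms, or
170 ms for the slow condition of the second experiment). Trials that never
reach within 5 mm of the 20 cm target distance are excluded as undershoots;
trials that merely miss the timing window are retained (only undershoot
exclusion is part of the protocol). All analysis latencies are relative to
detected vision onset; windows are half-open `[start, end)`.

Shift slopes use condition means per participant (not trial-level
regression). Dispersion ellipses are 1-SD ellipses, area = π·s₁·s₂ from the
singular values of the centered point cloud — any other coverage level
rescales all areas by a constant and preserves every comparison; they are
computed on no-shift rightward-load trials so the imposed shifts do not
inflate the spread. The force contrast is computed literally as
(right − none) − (left − none), which equals right − left algebraically;
the identity is asserted in tests to machine precision.

ANOVA (repeated-measures and mixed) is delegated to pingouin; the wrappers
enforce complete within designs, attach partial η² and the significance
labelling used throughout (within effects significant at p < 0.005, trends
at p < 0.05, between effects at 0.05), and expose Bonferroni-corrected
pairwise tests. A hand-computed sums-of-squares decomposition serves as the
independent oracle in the test suite, and a 1,000-table null simulation
checks the type-I rate.

## Onsets and bootstrap

The onset of a difference between paired trace ensembles is the first
sample at/after a search start where the pointwise paired two-tailed t-test
crosses p < 0.05, with an optional persistence requirement (consecutive
significant samples; default 1). The search starts at the feedback-removal
time (100 ms after vision onset) — searching earlier would only harvest
α-rate false crossings. Zero between-participant variance with a nonzero
mean is treated as a perfectly consistent difference (p = 0), so degenerate
bootstrap resamples behave sensibly; zero variance with zero mean raises an
error.

The bootstrap resamples participants with replacement and recomputes the
onset per resample (vectorized, chunked). The calibrated quantity is the
*between-condition onset difference*: the threshold-crossing estimator has
a detection-delay bias of order t_crit·σ/(a√n) that a single-onset
percentile CI cannot absorb, but the bias is common to both contrasts and
cancels in their difference. Coverage of the difference CI was verified at
~96% in a 300-replication calibration study (12 participants, ramp
divergence, 10-sample persistence).

## Synthetic-experiment generator

The generator reproduces the published design exactly: per speed session
6 blocks × 64 trials — 48 rightward-load trials (4 repetitions of
4 uncertainties × 3 shifts), 8 leftward, 8 load-free — randomized within
block; 768 regular trials per participant plus appended EMG calibration
trials; sessions at both speeds; viewing durations of 100 ms (and 170 ms
for slow sessions of experiment 2).

Kinematics ride on the noise-free LQG trajectories of the matching
speed/load condition, resampled from the 10 ms model grid to 1 kHz. The
visually driven correction is injected as a logistic-in-time lateral
displacement with asymptote −w(σ)·shift; the weights
w = {0.75, 0.55, 0.35, 0} for low/medium/high/no vision are the ground
truth and sit in the range of empirically observed asymptotic slopes
(−0.5…−0.75). The logistic rate is speed-dependent (faster rise for fast
movements), which switches the transient speed effect on; setting the rates
equal switches it off for null testing. The second time derivative of the
injected displacement (times the 1 kg hand mass) is added to the lateral
force channel, so force contrasts inherit the speed scaling physically. EMG
channels are envelope-modulated Gaussian broadband carriers: the agonist
(PM) envelope carries a load-locked burst and a shift-signed visual
response starting exactly 100 ms after vision onset, scaled by w(σ) and a
speed gain (1.3 fast / 1.0 slow); the antagonist (PD) carries no visual
response. Calibration envelopes scale with the participant's gain but not
with the speed gain, so normalization cancels participant heterogeneity
while preserving the speed effect — mirroring how calibration normalization
works on real EMG. Participant random effects are mean-corrected lognormals
(Gaussian on log-gains, σ = 0.12 on weights, 0.10 on EMG gain), so group
expectations equal the stored ground truth exactly. Undershoots are
injected at an exact per-session fraction (default 2%) by scaling the
forward trajectory below the target distance.

What the generator does not emulate: real EMG spectral structure beyond
band-limited noise, sensory delays, trial-to-trial adaptation, biomechanical
nonlinearity, or any coupling between the injected visual correction and
the load response. Passing recovery tests therefore demonstrates that the
pipeline measures what the generator encodes — weights, latencies, counts,
exclusions — not that the model fits human data.

Recovery is asserted against simultaneous 95% confidence intervals
(Bonferroni across the 8 condition cells): with eight independent per-cell
95% CIs the joint check would fail for ~1/3 of seeds by construction, which
is a property of the multiple-comparison arithmetic, not of the pipeline.

## Problem sizes and defaults

Simulated ensembles use the protocol's 25 runs per cell (600 trials for the
full grid, seconds of runtime). The recovery study uses the full
16-participant, 6-block design streamed participant-by-participant; the
statistical calibration uses 1,000 null ANOVA tables and 200 bootstrap
replications at 1,000 iterations. The demonstration driver
`03_generate_synthetic_experiment.py` defaults to a 4-participant,
2-block dataset so its CSV output stays small; all sizes are flags.

## Known limitations

* The additive-noise model separates estimation and control exactly; the
  signal-dependent variant approximates the coupled problem along the
  nominal trajectory rather than solving it iteratively.
* No sensory delays: simulated visual responses begin immediately after the
  jump, earlier than the ~100 ms physiological latency (the generator, by
  contrast, injects the latency explicitly).
* The model's slope asymptote is −1 by construction of the cursor-error
  cost; empirical slopes saturate at −0.5…−0.75, and no attempt is made to
  reproduce that divergence.
* The single-onset bootstrap CI inherits the detection-delay bias discussed
  above; only onset differences should be interpreted inferentially.
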