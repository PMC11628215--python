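# Default simulation configuration.
#
# Plant and protocol constants follow the published task (point mass, 9 N
# rightward load at 0.5 cm, +/-2 cm cursor jump at 8 cm, 400/700 ms movements
# plus 500 ms stabilization, 25 runs per cell). Noise magnitudes are model
# calibration constants: the Kalman gains depend only on their ratios, which
# were chosen so that the fast / low-uncertainty shift-slope converges near
# -1 within ~300-400 ms of the jump; the free overall scale is set small so
# that 25-run ensemble readouts carry negligible Monte-Carlo error, as in
# the published simulated traces. q_pos reproduces sub-mm endpoints and
# realistic peak forward velocities (~0.67 / 0.41 m/s fast/slow).
schema: reach-ofc-config
version: "1.0"
plant:
  mass: 1.0        # kg
  damping: 0.1     # N.s/m
  tau: 0.066       # s, muscle low-pass time constant
  dt: 0.01         # s, Euler step
  dims: 2
noise:
  motor_sd: 0.01    # N per step, additive noise on commanded force
  obs_sd:           # sensory SDs per observed channel
    pos: 0.0005     # m   (proprioceptive position)
    vel: 0.005      # m/s (proprioceptive velocity)
    f_com: 0.05     # N
    f_ext: 0.02     # N
    p_cursor: 0.007 # m, baseline visual SD before the uncertainty scaling
  visual_scales:   # variance scaling of the cursor channel per condition
    low: 0.1
    medium: 1.0
    high: 10.0
    inf: .inf      # no-vision condition: cursor gains exactly zero
  f_off: 0.001     # pseudo process-noise fraction on the cursor-hand offset
  f_ext: 0.01      # pseudo process-noise fraction on the external force
cost:
  control_penalty: 1.0e-4
  q_pos: 10.0
  q_vel: 0.0
  stab_duration: 0.5   # s
protocol:
  movement_times:      # s
    fast: 0.4
    slow: 0.7
  target_distance: 0.20  # m
  load: 9.0              # N, rightward
  load_trigger_y: 0.005  # m
  jump_sizes: [-0.02, 0.0, 0.02]  # m
  jump_trigger_y: 0.08   # m
  n_runs: 25
seed: 0
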