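"""Single-trial simulation of perturbed reaches.

A trial is a forward pass of the closed loop: the controller acts on the
Kalman estimate (or on the true state in the fully observable variant), the
plant integrates the control plus motor noise, and two scripted perturbations
fire on position triggers -- a constant rightward load as soon as the hand
leaves the start (y > 0.5 cm) and a lateral cursor jump when the hand crosses
the vision-onset distance (y >= 8 cm). The estimator never observes the
cursor-hand offset directly; it has to infer the jump from cursor
innovations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cost import CostModel
from .gains import (GainSchedules, compute_control_gains, compute_kalman_gains,
                    riccati_predict_update, stationary_prior_cov, _estimated_states,
                    _zero_no_vision, _INF_VISUAL_SCALE)
from .noise import NoiseModel
from .plant import InvalidParameterError, SystemMatrices


class EmptyResultError(ValueError):
    """Raised when an analysis is requested on an ensemble lacking the
    required condition (e.g. error decay without any jump trials)."""


@dataclass(frozen=True)
class TrialProtocol:
    """Timing and perturbation script of one simulated trial (SI units)."""

    movement_time: float = 0.4
    target_distance: float = 0.20
    load: float = 9.0
    load_trigger_y: float = 0.005
    jump_size: float = 0.0
    jump_trigger_y: float = 0.08
    stab_duration: float = 0.5
    n_runs: int = 25

    def __post_init__(self) -> None:
        if self.movement_time <= 0 or self.stab_duration < 0:
            raise InvalidParameterError("durations must be positive")
        if self.n_runs < 1:
            raise InvalidParameterError("n_runs must be >= 1")

    def n_steps(self, dt: float) -> int:
        return int(round((self.movement_time + self.stab_duration) / dt))

    def with_jump(self, jump_size: float) -> "TrialProtocol":
        from dataclasses import replace
        return replace(self, jump_size=jump_size)


@dataclass
class SimTrace:
    """Time series of one simulated trial (time grid shared by all series)."""

    t: np.ndarray
    x: np.ndarray            # true state, (N+1, n_x)
    xhat: np.ndarray         # posterior estimate
    xhat_prior: np.ndarray   # one-step prediction
    y: np.ndarray            # observations, (N+1, n_y)
    u: np.ndarray            # control, (N, n_u)
    lateral_force: np.ndarray  # f_com_x + f_ext_x, (N+1,)
    load_step: int | None
    jump_step: int | None
    layout: object = field(repr=False, default=None)


def simulate_trial(protocol: TrialProtocol, gains: GainSchedules,
                   sys: SystemMatrices, noise: NoiseModel,
                   seed: int | np.random.SeedSequence | None = 0,
                   noise_free: bool = False,
                   fully_observable: bool = False) -> SimTrace:
    """Simulate one trial; bit-reproducible for a fixed seed."""
    layout = sys.layout
    if layout.dims != 2:
        raise InvalidParameterError("trial simulation requires the 2-D plant")
    dt = sys.plant.dt
    n = protocol.n_steps(dt)
    if gains.horizon != n:
        raise InvalidParameterError(
            f"gain schedules computed for horizon {gains.horizon}, trial needs {n}")
    rng = np.random.default_rng(seed)
    nx, ny, nu = layout.n_states, layout.n_obs, sys.B.shape[1]

    ipy = layout.index("pos", 1)
    ify = layout.index("f_ext", 1)
    ifx = layout.index("f_ext", 0)
    ioffx = layout.index("p_offset", 0)
    icx = layout.index("f_com", 0)
    icom = [layout.index("f_com", ax) for ax in range(2)]
    obs_sd = np.sqrt(np.diag(noise.sensory_cov(layout, inf_as=1.0)))

    x = np.zeros((n + 1, nx))
    xhat = np.zeros((n + 1, nx))
    prior = np.zeros((n + 1, nx))
    yobs = np.zeros((n + 1, ny))
    u = np.zeros((n, nu))
    x[0, layout.index("p_target", 1)] = protocol.target_distance
    xhat[0] = x[0]
    prior[0] = x[0]
    yobs[0] = sys.H @ x[0]
    load_step: int | None = None
    jump_step: int | None = None

    for t in range(n):
        src = x[t] if fully_observable else xhat[t]
        u[t] = -gains.L[t] @ src
        xn = sys.A @ x[t] + sys.B @ u[t]
        if not noise_free:
            motor_sd = noise.motor_sd + noise.c_motor * np.abs(u[t])
            xn[icom] += rng.normal(0.0, 1.0, size=2) * motor_sd
        # scripted perturbations act on the true state only
        if load_step is None and xn[ipy] > protocol.load_trigger_y:
            xn[ifx] = protocol.load
            load_step = t + 1
        if jump_step is None and xn[ipy] >= protocol.jump_trigger_y:
            xn[ioffx] = protocol.jump_size
            jump_step = t + 1
        x[t + 1] = xn

        yt = sys.H @ xn
        if not noise_free:
            sd = obs_sd
            if noise.c_sensory:
                sd = obs_sd + noise.c_sensory * np.abs(yt)
            yt = yt + rng.normal(0.0, 1.0, size=ny) * sd
        yobs[t + 1] = yt
        p = sys.A @ xhat[t] + sys.B @ u[t]
        prior[t + 1] = p
        xhat[t + 1] = p + gains.K[t] @ (yt - sys.H @ p)

    return SimTrace(t=np.arange(n + 1) * dt, x=x, xhat=xhat, xhat_prior=prior,
                    y=yobs, u=u,
                    lateral_force=x[:, icx] + x[:, ifx],
                    load_step=load_step, jump_step=jump_step, layout=layout)


def run_condition(protocol: TrialProtocol, gains: GainSchedules,
                  sys: SystemMatrices, noise: NoiseModel,
                  n_runs: int | None = None,
                  master_seed: int | np.random.SeedSequence = 0,
                  noise_free: bool = False,
                  fully_observable: bool = False) -> list[SimTrace]:
    """Ensemble of trials with per-run seeds derived from ``master_seed``."""
    n_runs = protocol.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise InvalidParameterError("n_runs must be >= 1")
    if not isinstance(master_seed, np.random.SeedSequence):
        master_seed = np.random.SeedSequence(master_seed)
    children = master_seed.spawn(n_runs)
    return [simulate_trial(protocol, gains, sys, noise, seed=s,
                           noise_free=noise_free, fully_observable=fully_observable)
            for s in children]


def estimation_error_decay(ensemble: list[SimTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Mean (estimated − true) lateral cursor-hand offset, aligned to the jump.

    Returns (time-from-jump, mean error curve) averaged across the runs of the
    ensemble. Requires jump trials.
    """
    jumps = [tr for tr in ensemble if tr.jump_step is not None]
    if not jumps:
        raise EmptyResultError("estimation-error decay requires jump trials")
    layout = jumps[0].layout
    ioffx = layout.index("p_offset", 0)
    length = min(len(tr.t) - tr.jump_step for tr in jumps)
    errs = np.stack([ (tr.xhat[:, ioffx] - tr.x[:, ioffx])[tr.jump_step:tr.jump_step + length]
                      for tr in jumps])
    dt = jumps[0].t[1] - jumps[0].t[0]
    return np.arange(length) * dt, errs.mean(axis=0)


def signal_dependent_gain_schedules(sys: SystemMatrices, cost: CostModel,
                                    noise: NoiseModel, protocol: TrialProtocol) -> GainSchedules:
    """Gain schedules for the signal-dependent-noise variant.

    The full noise-dependent optimal control problem needs an iterative
    solver; here the signal-dependent covariances are evaluated along the
    nominal (noise-free) trajectory of the additive model and plugged into
    the standard recursions, which yields genuinely time-varying Kalman
    gains while the control recursion is unchanged.
    """
    n = protocol.n_steps(sys.plant.dt)
    L = compute_control_gains(sys, cost, n)
    base = GainSchedules(L=L, K=compute_kalman_gains(sys, noise, n))
    if noise.c_motor == 0.0 and noise.c_sensory == 0.0:
        return base
    nominal = simulate_trial(protocol, base, sys, noise, noise_free=True)

    layout = sys.layout
    est = _estimated_states(layout)
    A = sys.A[np.ix_(est, est)]
    H = sys.H[:, est]
    scale = _INF_VISUAL_SCALE if noise.no_vision else noise.visual_scale
    base_obs_sd = np.sqrt(np.diag(noise.sensory_cov(layout, inf_as=1.0)))
    cursor_chan = np.zeros(layout.n_obs, dtype=bool)
    for ax in range(layout.dims):
        cursor_chan[layout.obs_index("p_cursor", ax)] = True

    def Q_at(t: int) -> np.ndarray:
        q = np.zeros(layout.n_states)
        for ax in range(layout.dims):
            sd = noise.motor_sd + noise.c_motor * abs(nominal.u[min(t, len(nominal.u) - 1), ax])
            q[layout.index("f_com", ax)] = sd ** 2
            q[layout.index("f_ext", ax)] = noise.f_ext * sd ** 2
            q[layout.index("p_offset", ax)] = noise.f_off * sd ** 2
        return np.diag(q)[np.ix_(est, est)]

    def R_at(t: int) -> np.ndarray:
        ynom = sys.H @ nominal.x[min(t, len(nominal.t) - 1)]
        sd = base_obs_sd + noise.c_sensory * np.abs(ynom)
        var = sd ** 2
        var[cursor_chan] *= scale
        return np.diag(var)

    P = stationary_prior_cov(A, H, Q_at(0), R_at(0))
    K = np.zeros((n, layout.n_states, layout.n_obs))
    for t in range(n):
        Kt, P = riccati_predict_update(P, A, H, Q_at(t + 1), R_at(t + 1))
        K[t][np.ix_(est, np.arange(layout.n_obs))] = Kt
    if noise.no_vision:
        _zero_no_vision(K, layout)
    return GainSchedules(L=L, K=K)
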