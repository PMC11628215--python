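"""Finite-horizon control gains and Kalman gains.

Control gains come from the standard backward Riccati recursion for the cost

    J = sum_t  x_{t+1}' Q_{t+1} x_{t+1} + u_t' R u_t,

so a stabilization-only state cost still produces nonzero gains throughout
the movement (the cost-to-go propagates backwards), and shorter horizons
produce larger gains at the same distance from the target -- the urgency
mechanism.

Kalman gains come from the estimator Riccati equation with the pseudo
process-noise terms injected (see `noise`). For the additive-noise model the
filter is run at its stationary regime: the gain schedule is the fixed point
of the forward recursion, which makes the estimation dynamics independent of
the movement horizon by construction. The forward recursion itself is exposed
for the signal-dependent-noise variant, where the covariances, and hence the
gains, genuinely vary along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .cost import CostModel
from .noise import NoiseModel
from .plant import InvalidParameterError, SystemMatrices

#: finite variance scale standing in for the no-vision cursor channel inside
#: the Riccati solve (the resulting gain columns are zeroed exactly afterwards)
_INF_VISUAL_SCALE = 1e6


@dataclass(frozen=True)
class GainSchedules:
    """Time-indexed control gains L (N, n_u, n_x) and Kalman gains
    K (N, n_x, n_y) for one horizon/noise condition."""

    L: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        if len(self.L) != len(self.K):
            raise InvalidParameterError("L and K schedules must share the horizon length")

    @property
    def horizon(self) -> int:
        return len(self.L)


def compute_control_gains(sys: SystemMatrices, cost: CostModel, n_steps: int) -> np.ndarray:
    """Backward Riccati pass; returns the (n_steps, n_u, n_x) gain schedule
    for the policy u_t = -L_t x̂_t."""
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    A, B = sys.A, sys.B
    R = cost.R(B.shape[1])
    Qs = cost.schedule(sys, n_steps)
    L = np.zeros((n_steps, B.shape[1], A.shape[0]))
    S = np.zeros_like(A)
    for t in range(n_steps - 1, -1, -1):
        W = Qs[t] + S  # cost-to-go applied at x_{t+1}
        BtW = B.T @ W
        L[t] = np.linalg.solve(R + BtW @ B, BtW @ A)
        S = A.T @ W @ (A - B @ L[t])
        S = 0.5 * (S + S.T)
    return L


def riccati_predict_update(P: np.ndarray, A: np.ndarray, H: np.ndarray,
                           Q: np.ndarray, Rw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One forward step of the estimator Riccati map.

    Takes the a-priori covariance at t, returns (K_t, a-priori covariance at
    t+1) for the update x̂_{t+1} = x̂p + K (y_{t+1} - H x̂p).
    """
    S = H @ P @ H.T + Rw
    K = np.linalg.solve(S.T, (P @ H.T).T).T
    Ppost = P - K @ H @ P
    Pnext = A @ Ppost @ A.T + Q
    return K, 0.5 * (Pnext + Pnext.T)


def stationary_prior_cov(A: np.ndarray, H: np.ndarray, Q: np.ndarray,
                         Rw: np.ndarray) -> np.ndarray:
    """Stationary a-priori covariance (filter DARE fixed point)."""
    try:
        P = scipy.linalg.solve_discrete_are(A.T, H.T, Q, Rw)
    except Exception:
        # fixed-point iteration fallback for marginal spectra
        P = Q + np.eye(len(A)) * np.trace(Q) / max(len(A), 1)
        for _ in range(200_000):
            _, Pn = riccati_predict_update(P, A, H, Q, Rw)
            if np.max(np.abs(Pn - P)) < 1e-15 * (1.0 + np.max(np.abs(Pn))):
                return Pn
            P = Pn
    return 0.5 * (P + P.T)


def _estimated_states(layout) -> np.ndarray:
    """Indices of states the filter actually estimates (targets are known
    exactly and carry no noise, so they are excluded from the Riccati solve)."""
    keep = []
    for ax in range(layout.dims):
        for name in ("pos", "vel", "f_com", "f_ext", "p_cursor", "p_offset"):
            keep.append(layout.index(name, ax))
    return np.array(sorted(keep))


def compute_kalman_gains(sys: SystemMatrices, noise: NoiseModel, n_steps: int,
                         P0: np.ndarray | None = None) -> np.ndarray:
    """(n_steps, n_x, n_y) Kalman-gain schedule for the additive-noise model.

    The recursion is initialized at its stationary point (P0=None), so the
    schedule is constant in time; passing an explicit P0 runs the plain
    forward recursion from there instead.
    """
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    layout = sys.layout
    est = _estimated_states(layout)
    A = sys.A[np.ix_(est, est)]
    H = sys.H[:, est]
    Q = noise.process_cov(layout, pseudo=True)[np.ix_(est, est)]
    Rw = noise.sensory_cov(layout, inf_as=_INF_VISUAL_SCALE)
    _check_psd(Q, "process covariance")
    _check_psd(Rw, "sensory covariance")
    if P0 is None:
        P = stationary_prior_cov(A, H, Q, Rw)
    else:
        P = P0[np.ix_(est, est)] if P0.shape[0] == layout.n_states else P0
    K = np.zeros((n_steps, layout.n_states, layout.n_obs))
    for t in range(n_steps):
        Kt, P = riccati_predict_update(P, A, H, Q, Rw)
        K[t][np.ix_(est, np.arange(layout.n_obs))] = Kt
    if noise.no_vision:
        _zero_no_vision(K, layout)
    return K


def _zero_no_vision(K: np.ndarray, layout) -> None:
    """Exact no-vision limit: the cursor-innovation columns vanish, and the
    offset state -- whose error is then uncoupled from every observed
    channel -- gets a zero gain row."""
    for ax in range(layout.dims):
        K[:, :, layout.obs_index("p_cursor", ax)] = 0.0
        K[:, layout.index("p_offset", ax), :] = 0.0


def _check_psd(M: np.ndarray, name: str) -> None:
    if np.min(np.linalg.eigvalsh(0.5 * (M + M.T))) < -1e-12:
        raise InvalidParameterError(f"{name} must be positive semidefinite")


def kalman_step(xhat: np.ndarray, u: np.ndarray, y: np.ndarray, K: np.ndarray,
                sys: SystemMatrices) -> tuple[np.ndarray, np.ndarray]:
    """One predict/correct cycle.

    Prediction x̂p = A x̂ + B u; correction adds K times the innovation
    (observation minus predicted observation at the same time index).
    Returns (posterior estimate, prior).
    """
    prior = sys.A @ xhat + sys.B @ np.atleast_1d(u)
    post = prior + K @ (y - sys.H @ prior)
    return post, prior


def compute_gain_schedules(sys: SystemMatrices, cost: CostModel, noise: NoiseModel,
                           n_steps: int) -> GainSchedules:
    """Bundle control and Kalman schedules for one condition."""
    return GainSchedules(L=compute_control_gains(sys, cost, n_steps),
                         K=compute_kalman_gains(sys, noise, n_steps))
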