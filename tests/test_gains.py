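"""Control and Kalman gain computation against independent oracles."""

import numpy as np
import pytest

from reach_ofc.ofc import (CostModel, NoiseModel, build_discrete_system,
                           compute_control_gains, compute_kalman_gains,
                           kalman_step, stationary_prior_cov)
from reach_ofc.ofc.gains import riccati_predict_update
from reach_ofc.ofc.plant import PlantParams


def _scalar_lqr_bruteforce(A, B, Q_terminal, R, x0, grid):
    """Exhaustive search over a control grid for the 1-step problem
    min x1^2 Q + u0^2 R."""
    costs = [(Q_terminal * (A * x0 + B * u) ** 2 + R * u ** 2, u) for u in grid]
    return min(costs)[1]


def test_one_step_scalar_gain_matches_bruteforce_search():
    """A=B=R=Q=1, N=1: optimal u = -x/2, i.e. L0 = 0.5."""
    # backward recursion on a degenerate 'system' assembled by hand
    A = np.array([[1.0]])
    B = np.array([[1.0]])
    S = np.array([[1.0]])       # terminal Q
    R = np.array([[1.0]])
    L0 = np.linalg.solve(R + B.T @ S @ B, B.T @ S @ A)
    assert L0[0, 0] == pytest.approx(0.5)
    for x0 in (1.0, -2.0, 0.3):
        grid = np.linspace(-3 * abs(x0), 3 * abs(x0), 120001)
        u_star = _scalar_lqr_bruteforce(1.0, 1.0, 1.0, 1.0, x0, grid)
        assert u_star == pytest.approx(-0.5 * x0, abs=1e-4)


def test_zero_state_cost_gives_zero_gains(system):
    cost = CostModel(q_pos=0.0, q_vel=0.0)
    L = compute_control_gains(system, cost, 30)
    np.testing.assert_allclose(L, 0.0)


def test_two_step_gain_matches_bruteforce(system):
    """Scalar 2-step horizon with terminal cost: joint grid search over
    (u0, u1) agrees with the Riccati feedback law."""
    a, b, q, r = 0.9, 0.5, 2.0, 0.3
    # Riccati by hand
    S = q
    L1 = b * S * a / (r + b * S * b)
    S1 = q * 0 + a * S * (a - b * L1)
    L0 = b * S1 * a / (r + b * S1 * b)
    x0 = 1.7
    grid = np.linspace(-6, 6, 2401)
    best = None
    for u0 in grid:
        x1 = a * x0 + b * u0
        u1 = -L1 * x1  # inner optimum is exactly the feedback law
        x2 = a * x1 + b * u1
        c = q * x2 ** 2 + r * (u0 ** 2 + u1 ** 2)
        if best is None or c < best[0]:
            best = (c, u0)
    assert best[1] == pytest.approx(-L0 * x0, abs=2 * (grid[1] - grid[0]))


def test_urgency_gains_larger_for_shorter_horizon(system, sim_config):
    """At the 8 cm crossing, the position-error gain of the 400 ms movement
    exceeds that of the 700 ms movement: the urgency mechanism."""
    lay = system.layout
    ipy = lay.index("pos", 1)
    gains = {}
    for speed, cross_step in (("fast", 25), ("slow", 38)):
        n = sim_config.protocol_for(speed).n_steps(0.01)
        L = compute_control_gains(system, sim_config.cost, n)
        gains[speed] = abs(L[cross_step, 1, ipy])
    assert gains["fast"] > gains["slow"]


def test_scalar_kalman_steady_state_closed_form():
    """Scalar system A=1, H=1: stationary prior variance solves
    P = P - P^2/(P+r) + q, i.e. P = (q + sqrt(q^2+4qr))/2, K = P/(P+r)."""
    for q, r in [(0.1, 1.0), (2.0, 0.5), (1e-4, 1e-2)]:
        A = np.array([[1.0]])
        H = np.array([[1.0]])
        P = stationary_prior_cov(A, H, np.array([[q]]), np.array([[r]]))
        P_exact = (q + np.sqrt(q * q + 4 * q * r)) / 2
        assert P[0, 0] == pytest.approx(P_exact, rel=1e-8)
        K, _ = riccati_predict_update(P, A, H, np.array([[q]]), np.array([[r]]))
        assert K[0, 0] == pytest.approx(P_exact / (P_exact + r), rel=1e-8)


def test_no_vision_zeroes_cursor_gain_columns(system):
    K = compute_kalman_gains(system, NoiseModel(visual_scale=np.inf), 5)
    lay = system.layout
    for ax in range(2):
        assert np.all(K[:, :, lay.obs_index("p_cursor", ax)] == 0.0)
    # and the offset state can then never be corrected
    assert np.all(K[:, lay.index("p_offset", 0), :] == 0.0)


def test_kalman_step_zero_innovation_returns_prior(system, rng):
    xhat = rng.normal(size=system.A.shape[0])
    u = rng.normal(size=2)
    K = rng.normal(size=(system.A.shape[0], system.H.shape[0])) * 0.1
    prior = system.A @ xhat + system.B @ u
    post, pr = kalman_step(xhat, u, system.H @ prior, K, system)
    np.testing.assert_allclose(post, prior, atol=1e-12)
    np.testing.assert_allclose(pr, prior)
    post0, _ = kalman_step(xhat, u, rng.normal(size=system.H.shape[0]),
                           np.zeros_like(K), system)
    np.testing.assert_allclose(post0, prior)


def _gaussian_conditioning_oracle(rng, n=3, m=2):
    """One filter cycle vs explicit joint-Gaussian conditioning on a random
    small system. Returns (kalman posterior mean, conditioned mean)."""
    A = rng.normal(size=(n, n)) * 0.5
    H = rng.normal(size=(m, n))
    Q = np.diag(rng.uniform(0.1, 1.0, n))
    R = np.diag(rng.uniform(0.1, 1.0, m))
    P0 = np.diag(rng.uniform(0.2, 2.0, n))      # posterior cov at t
    xhat0 = rng.normal(size=n)
    u = rng.normal(size=n)                       # treat Bu as known input
    y = rng.normal(size=m)
    # filter: predict then correct with the optimal gain
    x_prior = A @ xhat0 + u
    P_prior = A @ P0 @ A.T + Q
    K = P_prior @ H.T @ np.linalg.inv(H @ P_prior @ H.T + R)
    x_post = x_prior + K @ (y - H @ x_prior)
    # oracle: joint Gaussian of (x_{t+1}, y) conditioned on y
    Sxy = P_prior @ H.T
    Syy = H @ P_prior @ H.T + R
    x_cond = x_prior + Sxy @ np.linalg.solve(Syy, y - H @ x_prior)
    return x_post, x_cond


def test_kalman_update_equals_gaussian_conditioning(rng):
    for _ in range(100):
        x_post, x_cond = _gaussian_conditioning_oracle(rng)
        np.testing.assert_allclose(x_post, x_cond, atol=1e-10)


def test_stationary_gain_schedule_is_time_constant(system, sim_config):
    K = compute_kalman_gains(system, sim_config.noise_for("low"), 40)
    np.testing.assert_allclose(K - K[:1], 0.0, atol=1e-9)


def test_jump_aligned_offset_gains_horizon_independent(system, sim_config):
    """The cursor-offset gain block does not depend on the movement horizon."""
    lay = system.layout
    ioff = lay.index("p_offset", 0)
    Ks = {}
    for speed in ("fast", "slow"):
        n = sim_config.protocol_for(speed).n_steps(0.01)
        Ks[speed] = compute_kalman_gains(system, sim_config.noise_for("low"), n)
    np.testing.assert_allclose(Ks["fast"][0, ioff], Ks["slow"][0, ioff], atol=1e-9)
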