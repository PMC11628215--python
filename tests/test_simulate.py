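"""Trial simulation: perturbation script, determinism, estimator behavior."""

import numpy as np
import pytest

from reach_ofc.ofc import (EmptyResultError, NoiseModel, TrialProtocol,
                           estimation_error_decay, make_signal_dependent_noise,
                           run_condition, signal_dependent_gain_schedules,
                           simulate_trial)
from reach_ofc.ofc.gains import GainSchedules, compute_control_gains, compute_kalman_gains


def test_unperturbed_noise_free_reach_hits_target(system, sim_config, default_gains):
    proto = TrialProtocol(movement_time=0.4, load=0.0, jump_size=0.0)
    tr = simulate_trial(proto, default_gains[("fast", "low")], system,
                        sim_config.noise_for("low"), noise_free=True)
    lay = system.layout
    assert np.allclose(tr.x[:, lay.index("pos", 0)], 0.0, atol=1e-12)
    assert abs(tr.x[-1, lay.index("pos", 1)] - 0.20) < 1e-3
    assert tr.jump_step is not None            # vision-onset analog still fires


def test_opposite_jumps_mirror_symmetric(system, sim_config, default_gains):
    lay = system.layout
    traces = {}
    for j in (+0.02, -0.02):
        proto = TrialProtocol(movement_time=0.4, load=0.0, jump_size=j)
        traces[j] = simulate_trial(proto, default_gains[("fast", "low")], system,
                                   sim_config.noise_for("low"), noise_free=True)
    np.testing.assert_allclose(traces[0.02].x[:, lay.index("pos", 0)],
                               -traces[-0.02].x[:, lay.index("pos", 0)], atol=1e-12)


def test_fixed_seed_reproducible(system, sim_config, fast_low):
    proto, gains, noise = fast_low
    a = simulate_trial(proto.with_jump(0.02), gains, system, noise, seed=42)
    b = simulate_trial(proto.with_jump(0.02), gains, system, noise, seed=42)
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.y, b.y)
    c = simulate_trial(proto.with_jump(0.02), gains, system, noise, seed=43)
    assert not np.array_equal(a.x, c.x)


def test_perturbation_triggers_fire_once_and_hold(system, sim_config, fast_low):
    proto, gains, noise = fast_low
    tr = simulate_trial(proto.with_jump(0.02), gains, system, noise, noise_free=True)
    lay = system.layout
    fe = tr.x[:, lay.index("f_ext", 0)]
    off = tr.x[:, lay.index("p_offset", 0)]
    assert np.all(fe[: tr.load_step] == 0.0) and np.all(fe[tr.load_step:] == 9.0)
    assert np.all(off[: tr.jump_step] == 0.0) and np.all(off[tr.jump_step:] == 0.02)
    assert tr.load_step < tr.jump_step


def test_gain_horizon_mismatch_rejected(system, sim_config, default_gains):
    proto = TrialProtocol(movement_time=0.7)
    with pytest.raises(Exception, match="horizon"):
        simulate_trial(proto, default_gains[("fast", "low")], system,
                       sim_config.noise_for("low"))


def test_ensemble_seeding_and_lln(system, sim_config, fast_low):
    proto, gains, noise = fast_low
    lay = system.layout
    icx = lay.index("f_com", 0)
    e1 = run_condition(proto, gains, system, noise, n_runs=5, master_seed=9)
    e2 = run_condition(proto, gains, system, noise, n_runs=5, master_seed=9)
    for a, b in zip(e1, e2):
        np.testing.assert_array_equal(a.x, b.x)
    nf = simulate_trial(proto, gains, system, noise, noise_free=True)
    err = {}
    for n in (25, 400):
        ens = run_condition(proto, gains, system, noise, n_runs=n, master_seed=1)
        mean_force = np.mean([t.lateral_force for t in ens], axis=0)
        err[n] = np.max(np.abs(mean_force - nf.lateral_force))
    assert err[400] < err[25]          # Monte-Carlo error shrinks with n
    assert err[400] < 5 * noise.motor_sd / np.sqrt(400) * 10


def test_estimation_error_decay_contract(system, sim_config, default_gains):
    proto = TrialProtocol(movement_time=0.4, load=0.0, jump_size=0.0)
    tr = simulate_trial(proto, default_gains[("fast", "low")], system,
                        sim_config.noise_for("low"), noise_free=True)
    # a no-jump trial still records the 8 cm crossing, but the offset error is 0
    t, err = estimation_error_decay([tr])
    np.testing.assert_allclose(err, 0.0, atol=1e-14)
    with pytest.raises(EmptyResultError):
        estimation_error_decay([])


def test_fully_observable_policy(system, sim_config, default_gains):
    """Control from the true state: vision is never used, so traces are
    identical across visual scales for identical noise draws, while the
    speed effect on the jump force response survives."""
    lay = system.layout
    proto = TrialProtocol(movement_time=0.4, jump_size=0.02)
    tr = {}
    for unc in ("low", "inf"):
        tr[unc] = simulate_trial(proto, default_gains[("fast", unc)], system,
                                 sim_config.noise_for(unc), seed=3,
                                 fully_observable=True)
    np.testing.assert_allclose(tr["low"].x, tr["inf"].x, atol=1e-12)
    # u_t = -L_t x_t exactly
    g = default_gains[("fast", "low")]
    for t in (5, 40):
        np.testing.assert_allclose(tr["low"].u[t], -g.L[t] @ tr["low"].x[t])
    peaks = {}
    for speed in ("fast", "slow"):
        proto = sim_config.protocol_for(speed)
        f = {}
        for j in (0.02, -0.02):
            x = simulate_trial(proto.with_jump(j), default_gains[(speed, "low")],
                               system, sim_config.noise_for("low"),
                               noise_free=True, fully_observable=True)
            f[j] = x.lateral_force[x.jump_step:]
        m = min(len(f[0.02]), len(f[-0.02]))
        peaks[speed] = np.max(np.abs(f[0.02][:m] - f[-0.02][:m]))
    assert peaks["fast"] > peaks["slow"]


def test_signal_dependent_noise_reduces_to_additive(system, sim_config):
    noise = sim_config.noise_for("low")
    sd0 = make_signal_dependent_noise(noise, 0.0, 0.0)
    proto = sim_config.protocol_for("fast", jump_size=0.02)
    g_add = signal_dependent_gain_schedules(system, sim_config.cost, noise, proto)
    g_sd0 = signal_dependent_gain_schedules(system, sim_config.cost, sd0, proto)
    np.testing.assert_allclose(g_add.K, g_sd0.K)
    a = simulate_trial(proto, g_add, system, noise, seed=5)
    b = simulate_trial(proto, g_sd0, system, sd0, seed=5)
    np.testing.assert_array_equal(a.x, b.x)
    with pytest.raises(Exception):
        make_signal_dependent_noise(noise, -0.1, 0.0)


def test_signal_dependent_motor_noise_scales_with_control(system, sim_config):
    """With c_motor > 0, the across-run spread of the commanded force is
    larger in high-|u| epochs than in low-|u| epochs."""
    noise = make_signal_dependent_noise(sim_config.noise_for("low"), 0.5, 0.0)
    proto = sim_config.protocol_for("fast")
    gains = signal_dependent_gain_schedules(system, sim_config.cost, noise, proto)
    ens = run_condition(proto, gains, system, noise, n_runs=60, master_seed=2)
    lay = system.layout
    ic = lay.index("f_com", 1)
    # per-step process-noise residuals on the forward commanded force
    resid, absu = [], []
    for tr in ens:
        pred = (system.A @ tr.x[:-1].T).T + (system.B @ tr.u.T).T
        resid.append(tr.x[1:, ic] - pred[:, ic])
        absu.append(np.abs(tr.u[:, 1]))
    resid = np.stack(resid)
    mean_u = np.stack(absu).mean(axis=0)
    hi = mean_u > np.quantile(mean_u, 0.8)
    lo = mean_u < np.quantile(mean_u, 0.2)
    assert resid[:, hi].std() > 2 * resid[:, lo].std()


def test_signal_dependent_gains_are_time_varying(system, sim_config):
    noise = make_signal_dependent_noise(sim_config.noise_for("low"), 0.5, 0.5)
    proto = sim_config.protocol_for("fast", jump_size=0.02)
    g = signal_dependent_gain_schedules(system, sim_config.cost, noise, proto)
    assert np.max(np.abs(g.K - g.K[:1])) > 1e-6
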