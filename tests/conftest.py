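import numpy as np
import pytest

from reach_ofc import SimulationConfig
from reach_ofc.ofc import (GainSchedules, build_discrete_system,
                           compute_control_gains, compute_kalman_gains)
from reach_ofc.synth import SynthConfig, generate_experiment


@pytest.fixture(scope="session")
def system():
    return build_discrete_system()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig.default()


@pytest.fixture(scope="session")
def default_gains(system, sim_config):
    """Gain schedules per (speed, uncertainty) for the default config."""
    out = {}
    for speed in ("fast", "slow"):
        proto = sim_config.protocol_for(speed)
        n = proto.n_steps(sim_config.plant.dt)
        L = compute_control_gains(system, sim_config.cost, n)
        for unc in ("low", "medium", "high", "inf"):
            K = compute_kalman_gains(system, sim_config.noise_for(unc), n)
            out[(speed, unc)] = GainSchedules(L=L, K=K)
    return out


@pytest.fixture(scope="session")
def fast_low(system, sim_config, default_gains):
    proto = sim_config.protocol_for("fast")
    return proto, default_gains[("fast", "low")], sim_config.noise_for("low")


@pytest.fixture(scope="session")
def small_synth():
    """Compact synthetic experiment: 4 participants, 2 blocks per session."""
    cfg = SynthConfig(n_participants=4, n_blocks=2, master_seed=11)
    samples, meta, truth = generate_experiment(cfg)
    return cfg, samples, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
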