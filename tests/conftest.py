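from dataclasses import replace

import pytest

from memcpg import CircuitConfig, calibrate_delays, run_learning


@pytest.fixture(scope="session")
def config():
    """Default calibrated circuit configuration."""
    return CircuitConfig()


@pytest.fixture(scope="session")
def tuned_dual_config():
    """Dual-plastic circuit with delay compensation applied."""
    cfg = CircuitConfig(mode="dual", initial_resistance={"pink": 70.0, "green": 120.0})
    return replace(cfg, delays=calibrate_delays(cfg))


@pytest.fixture(scope="session")
def dual_learning_run(tuned_dual_config):
    """Full dual-plastic self-learning run (pink 70, green 120 kOhm)."""
    return run_learning(tuned_dual_config, n_trials=200)


@pytest.fixture(scope="session")
def single_learning_run():
    """Full single-plastic self-learning run (green from 170 kOhm)."""
    cfg = CircuitConfig(mode="single", initial_resistance={"pink": 170.0, "green": 170.0})
    return run_learning(cfg, n_trials=200)
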