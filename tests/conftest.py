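"""Shared fixtures: thermal environment, default network, simulated batches.

The full-scale multi-speed dataset (1000 curves per speed at the four
modelled pulling speeds) is session-scoped and lazily built, so only the
tests that need the complete study conditions pay for it.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from catchkit.config import RunConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
from catchkit.elasticity import Environment
from catchkit.pipeline import simulate_and_analyze
from catchkit.simulate import default_network

STUDY_SEED = 7
SMALL_SEED = 11


@pytest.fixture(scope="session")
def env() -> Environment:
    return Environment()


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def study_config() -> RunConfig:
    cfg = RunConfig(seed=STUDY_SEED)
    cfg.save_curves = False
    return cfg


@pytest.fixture(scope="session")
def study_frame(study_config):
    """Full study conditions: 1000 curves per speed at
    {100, 400, 1600, 6400} nm/s, simulated and analyzed."""
    return simulate_and_analyze(study_config, n_curves=1000)


@pytest.fixture(scope="session")
def small_frame(study_config):
    """Light batch for per-curve analysis tests: 150 curves at 400 nm/s."""
    return simulate_and_analyze(study_config, speeds=(400.0,),
                                n_curves=150, seed=SMALL_SEED)
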