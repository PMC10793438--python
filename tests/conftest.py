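import dataclasses

import numpy as np
import pytest

from p16mave import SimulationConfig, simulate_celltag_control


@pytest.fixture
def config():
    """Default study conditions."""
    return SimulationConfig()


@pytest.fixture
def toy_config():
    """Five-residue screen at reduced depth for fast end-to-end tests."""
    return SimulationConfig(n_residues=5, depth_init=20_000, depth_cf=20_000)


@pytest.fixture
def noise_free_config():
    """Deterministic growth with sampling as the only stochastic element."""
    return SimulationConfig(bottleneck_sd=0.0, growth_noise_sd=0.0)


@pytest.fixture
def control_tables(config):
    return simulate_celltag_control(config, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
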