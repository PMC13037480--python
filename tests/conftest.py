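import numpy as np
import pytest

from hydrotraits.synth import GeneratorConfig, default_truth


@pytest.fixture
def truth():
    return default_truth()


@pytest.fixture
def quiet_cfg():
    """Zero-noise generator config for exact round trips."""
    return GeneratorConfig(
        noise_mass_g=0.0, noise_leaf_mass_g=0.0, noise_psi_mpa=0.0,
        noise_pressure_kpa=0.0, noise_a_rel=0.0, noise_circ_mm=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
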