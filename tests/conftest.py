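import numpy as np
import pytest

from kinegen.synthetic import JumpSimConfig, simulate_jump_trial


@pytest.fixture(scope="session")
def cmj_trial():
    """Noise-free countermovement jump at default study conditions."""
    return simulate_jump_trial(JumpSimConfig(jump_type="CMJ"))


@pytest.fixture(scope="session")
def sj_trial():
    return simulate_jump_trial(JumpSimConfig(jump_type="SJ"))


@pytest.fixture(scope="session")
def dj_trial():
    return simulate_jump_trial(JumpSimConfig(jump_type="DJ"))


@pytest.fixture(scope="session")
def noisy_cmj_trial():
    """CMJ with 2 mm marker jitter, the upper end of optical-capture noise."""
    return simulate_jump_trial(JumpSimConfig(jump_type="CMJ", noise_sd=0.002, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
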