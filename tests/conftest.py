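import numpy as np
import pytest

from posturadapt import SynthConfig, generate_trial


@pytest.fixture(scope="session")
def lf_clean_trial():
    """Noiseless LF protocol trial with perfect head-pelvis coordination."""
    return generate_trial(SynthConfig(noise_sd=0.0, coordination=1.0, seed=7))


@pytest.fixture(scope="session")
def hf_clean_trial():
    """Noiseless HF protocol trial (31 cycles at 0.56 Hz)."""
    return generate_trial(SynthConfig.hf(noise_sd=0.0, coordination=1.0, seed=7))


@pytest.fixture(scope="session")
def lf_noisy_trial():
    """LF trial with default measurement noise (5% of each asymptote)."""
    return generate_trial(SynthConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
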