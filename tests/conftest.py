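import numpy as np
import pytest

from fmgdecode import SimConfig, simulate_dataset, simulate_trial


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small noiseless cohort: deterministic pressures, fast to window."""
    return SimConfig(
        n_subjects=2,
        n_trials_per_subject=3,
        seconds_per_finger=2.5,
        noise_sd=0.0,
        drift_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_trials(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def noisy_config() -> SimConfig:
    """Same shape with the default noise/drift levels."""
    return SimConfig(
        n_subjects=2,
        n_trials_per_subject=3,
        seconds_per_finger=2.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_trials(noisy_config):
    return simulate_dataset(noisy_config)


@pytest.fixture(scope="session")
def one_trial(tiny_config):
    return simulate_trial(tiny_config, 0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
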