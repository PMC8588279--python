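import numpy as np
import pytest

from atcurve.pipeline import detect_trial_events
from atcurve.simulate import SimulationParams, simulate_trial


@pytest.fixture(scope="session")
def walking_trial():
    """Small noisy walking trial (3 strides) shared across tests."""
    return simulate_trial(SimulationParams(mode="walking", n_strides=3, seed=7))


@pytest.fixture(scope="session")
def clean_walking_trial():
    """Noise-free walking trial: measured path lies exactly on the analytic arc."""
    return simulate_trial(
        SimulationParams(mode="walking", n_strides=3, noise_sigma=0.0, pixel_noise=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def running_trial():
    return simulate_trial(SimulationParams(mode="slow_run", n_strides=3, seed=11))


@pytest.fixture(scope="session")
def walking_events(walking_trial):
    return detect_trial_events(walking_trial.markers, "walking")


@pytest.fixture(scope="session")
def clean_walking_events(clean_walking_trial):
    return detect_trial_events(clean_walking_trial.markers, "walking")


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
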