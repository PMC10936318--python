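import numpy as np
import pytest

import sockgait as sg


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless 60 s trial at 0.89 m/s with a 25-sample injected lag."""
    cfg = sg.SyntheticConfig(speed=0.89, duration=60.0, seed=5, lag=25, noise_frac=0.0)
    return sg.simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """Same trial at 5% per-channel measurement noise."""
    cfg = sg.SyntheticConfig(speed=0.89, duration=60.0, seed=5, lag=25, noise_frac=0.05)
    return sg.simulate_trial(cfg)


@pytest.fixture(scope="session")
def clean_aligned(clean_trial):
    return sg.preprocess_trial(clean_trial)


@pytest.fixture(scope="session")
def noisy_aligned(noisy_trial):
    return sg.preprocess_trial(noisy_trial)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
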