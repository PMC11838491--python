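import numpy as np
import pytest

from synbmi.signals import blank_artifact_windows
from synbmi.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A small masked session used by decoding/experiment tests."""
    cfg = SynthConfig(n_neural_channels=16, n_trials=60, seed=7)
    sess, truth = generate_session(cfg)
    return blank_artifact_windows(sess), truth, cfg


@pytest.fixture(scope="session")
def clean_emg_session():
    """Noiseless-EMG session with 3 latents for recovery tests."""
    cfg = SynthConfig(n_neural_channels=16, n_trials=60,
                      emg_noise_sd=0.0, seed=1)
    sess, truth = generate_session(cfg)
    return sess, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
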