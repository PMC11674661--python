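import numpy as np
import pytest

from mieeg.containers import Montage
from mieeg.synth import SyntheticConfig, generate_subject

#: artifact-free generator settings shared by tests that need clean data
CLEAN_RATES = {"blink": 0.0, "emg": 0.0, "global_bad_channel": 0.0,
               "epoch_bad_channel": 0.0}


@pytest.fixture(scope="session")
def montage():
    return Montage.physionet64()


@pytest.fixture(scope="session")
def clean_config():
    return SyntheticConfig(n_subjects=2, trials_per_subject=30, snr=0.5,
                           artifact_rates=CLEAN_RATES, line_noise_amp=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_subject(clean_config):
    """30 artifact-free epochs of 64 x 320."""
    epochs, gt = generate_subject(clean_config, 0)
    return epochs, gt


@pytest.fixture(scope="session")
def default_subject():
    """Epochs with the default artifact injection rates."""
    cfg = SyntheticConfig(n_subjects=1, trials_per_subject=40, snr=0.5, seed=21)
    return generate_subject(cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
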