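import numpy as np
import pytest

from sigcpc.data import SynthConfig, generate_dataset, split_dataset
from sigcpc.pretext import PretextConfig, train_pretext

#: small, fast dataset for unit tests
SMALL_CONFIG = SynthConfig(
    n_classes=3,
    n_per_class=20,
    epoch_length=64,
    sampling_rate=100.0,
    class_freqs=(4.0, 12.0, 25.0),
    class_amps=(1.0, 1.0, 1.0),
    noise_sd=0.2,
    seed=7,
)

#: the study conditions: 5 classes x 100 epochs of length 256, moderate noise
STUDY_CONFIG = SynthConfig(n_classes=5, n_per_class=100, epoch_length=256, seed=42)


@pytest.fixture
def small_dataset():
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def study_dataset():
    return generate_dataset(STUDY_CONFIG)


@pytest.fixture(scope="session")
def study_split(study_dataset):
    return split_dataset(study_dataset, 0.1, seed=42)


@pytest.fixture(scope="session")
def trained_pretext(study_split):
    """Pretext model trained at reduced scale (5 epochs x 200 iterations).

    Session-scoped: several tests probe the same trained encoder.
    """
    train, test = study_split
    config = PretextConfig(epochs=5, iterations_per_epoch=200, seed=0)
    model, history = train_pretext(train, test, config)
    return model, history
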