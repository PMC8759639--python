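import numpy as np
import pytest

from rsta import (
    balance_classes,
    bandpass_filter,
    baseline_correct,
    crop,
    generate_epochs,
)
from rsta.simulate import (
    Bump,
    NoiseSpec,
    SimulationConfig,
    SubjectVariability,
    TrialVariability,
    desk_scale_config,
)


def preprocess(epochs, seed=0):
    """Canonical conditioning chain: filter, baseline, crop, balance."""
    epochs = bandpass_filter(epochs, 1.0, 45.0)
    epochs = baseline_correct(epochs)
    epochs = crop(epochs, 0.0, 0.5)
    return balance_classes(epochs, seed=seed)


@pytest.fixture(scope="session")
def small_config():
    return desk_scale_config(seed=3, n_subjects=4, trials_per_class=(12, 24))


@pytest.fixture(scope="session")
def small_epochs(small_config):
    """Raw (unprocessed) small synthetic dataset."""
    return generate_epochs(small_config)


@pytest.fixture(scope="session")
def prepared_epochs(small_epochs):
    """Preprocessed and class-balanced small dataset."""
    return preprocess(small_epochs, seed=0)


def quiet_config(seed=0, **overrides):
    """Noise-free, jitter-free single-subject configuration."""
    params = dict(
        n_subjects=1,
        trials_per_class=(4, 4),
        sampling_rate=128.0,
        noise=NoiseSpec(background_sd_uv=0.0, sensor_sd_uv=0.0),
        subject_variability=SubjectVariability(0.0, 0.0, 0.0, 0.0),
        trial_variability=TrialVariability(0.0, 0.0),
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def random_spd(rng, n, scale=1.0):
    """Well-conditioned random SPD matrix."""
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))
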