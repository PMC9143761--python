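import numpy as np
import pytest

from gaitevents import SubjectSpec, simulate_trial


@pytest.fixture(scope="session")
def clean_subject():
    """Perfectly regular walker: 1 Hz cadence, no asymmetry, no noise."""
    return SubjectSpec(subject_id="S000", group="YA", gender="F",
                       cadence_hz=1.0, stance_fraction=0.6,
                       asymmetry=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_trial(clean_subject):
    return simulate_trial(clean_subject, speed="preferred", fs=200.0, seed=3)


@pytest.fixture(scope="session")
def noisy_subject():
    return SubjectSpec(subject_id="S001", group="PD", gender="M",
                       cadence_hz=0.9, stance_fraction=0.62,
                       asymmetry=0.04, noise_sd=0.06)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
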