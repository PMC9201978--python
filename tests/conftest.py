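import numpy as np
import pytest

from gaitevents import Kinematics, SyntheticGaitSpec, simulate_trial
from gaitevents.synthetic import make_validation_corpus


@pytest.fixture(scope="session")
def sw_walk():
    """Noiseless straight walk at comfortable speed (1.2 m/s), with its
    ground truth and a shared kinematics cache."""
    trial, truth = simulate_trial(SyntheticGaitSpec(n_strides=10, seed=1))
    return trial, truth, Kinematics(trial)


@pytest.fixture(scope="session")
def forefoot_walk():
    trial, truth = simulate_trial(
        SyntheticGaitSpec(n_strides=10, foot_strike="forefoot", seed=1))
    return trial, truth, Kinematics(trial)


@pytest.fixture(scope="session")
def corpus():
    return make_validation_corpus(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
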