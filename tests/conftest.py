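import numpy as np
import pytest

from drowsnet.preprocess import bandpass_filter, downsample, segment_epochs
from drowsnet.simulate import SimConfig, separable_config, simulate_session

SHORT_FLIGHT_S = 6.0
SHORT_WINDOW_S = 2.0


@pytest.fixture(scope="session")
def short_session():
    """Small but realistic session: 6 trials of 6 s flight + 2 s window at 200 Hz."""
    cfg = SimConfig(n_trials=6, trial_flight_s=SHORT_FLIGHT_S, kss_window_s=SHORT_WINDOW_S,
                    fs=200.0, seed=11, blink_rate=20.0)
    return simulate_session(cfg, subject_id="S1")


@pytest.fixture(scope="session")
def short_epochs(short_session):
    """The short session run through bandpass -> downsample -> segmentation."""
    session = downsample(bandpass_filter(short_session), 100.0)
    return segment_epochs(session, trial_flight_s=SHORT_FLIGHT_S, kss_window_s=SHORT_WINDOW_S)


@pytest.fixture(scope="session")
def separable_epochs():
    """Strongly level-separable epochs, 10 trials covering all five levels."""
    cfg = separable_config(n_trials=10, fs=200.0, trial_flight_s=SHORT_FLIGHT_S,
                           kss_window_s=SHORT_WINDOW_S, seed=5)
    session = downsample(bandpass_filter(simulate_session(cfg)), 100.0)
    return segment_epochs(session, trial_flight_s=SHORT_FLIGHT_S, kss_window_s=SHORT_WINDOW_S)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
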