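"""Shared fixtures: one small synthetic session reused across test modules.

The session is scaled down from the emulated study conditions (200 Hz
instead of 1 kHz, 4-s stimuli whose alpha response fills the decode window,
2-s rests, 10 trials per class) so the full pipeline runs in seconds while
keeping the 64-channel montage and the spatial-spectral structure intact.
"""

import numpy as np
import pytest

from eegmanifold import SessionConfig, alpha_epochs, generate_recording

SMALL = dict(
    fs=200.0,
    stim_duration=4.0,
    rest_duration=2.0,
    n_trials_per_class=10,
    response_fraction=1.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_session():
    cfg = SessionConfig(**SMALL)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def small_epochs(small_session):
    _, rec, _ = small_session
    return alpha_epochs(rec, cap=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
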