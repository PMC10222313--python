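import numpy as np
import pytest

from emgpix import SimConfig, default_profiles, generate_recording


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def short_cfg():
    """One-second holds: enough for 4 segments, fast to synthesize."""
    return SimConfig(n_subjects=1, n_repetitions=1, hold_duration=1.0, seed=42)


@pytest.fixture(scope="session")
def short_recording(profiles, short_cfg):
    return generate_recording(profiles[2], short_cfg, subject_id=0, repetition=0)


@pytest.fixture(scope="session")
def segment_500(short_recording):
    """A 16-channel, 500-sample (250 ms at 2000 sps) segment."""
    return short_recording.samples[:, :500].copy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
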