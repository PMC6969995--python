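import numpy as np
import pytest

import fatiguekit as fk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_emg_trial():
    """60 s EMG trial with ~1 s bursts every 2 s, drifting pass-band."""
    spec = fk.synth.SyntheticTrialSpec(duration_s=60.0, seed=1)
    sig, truth = fk.synth.synth_emg(spec)
    return sig, truth


@pytest.fixture(scope="session")
def clean_ecg_60bpm():
    """120 s noiseless ECG at a constant 60 bpm."""
    spec = fk.synth.SyntheticTrialSpec(
        duration_s=120.0, seed=2, rr_start=1.0, rr_slope=0.0,
        lf_amp=0.0, hf_amp=0.0, rr_noise_sd=0.0, ecg_noise_sd=0.0)
    return fk.synth.synth_ecg(spec)


@pytest.fixture(scope="session")
def drifting_tachogram():
    """300 s tachogram with a programmed negative mean-RR trend."""
    spec = fk.synth.SyntheticTrialSpec(duration_s=300.0, seed=5)
    return fk.synth.synth_rr(spec)
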