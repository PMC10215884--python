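import numpy as np
import pytest

import eegdenoiser as ed


@pytest.fixture(scope="session")
def small_banks():
    """Small surrogate banks sharing the canonical band limits."""
    eeg = ed.generate_surrogate_bank(ed.SurrogateSpec(
        "EEG", count=24, length=512, fs=256, passband=(1, 80),
        spectral_exponent=1.0, amplitude_scale=10, seed=11))
    eog = ed.generate_surrogate_bank(ed.SurrogateSpec(
        "EOG", count=20, length=512, fs=256, passband=(0.3, 10),
        spectral_exponent=1.5, amplitude_scale=15, seed=12))
    emg = ed.generate_surrogate_bank(ed.SurrogateSpec(
        "EMG", count=30, length=1024, fs=512, passband=(1, 120),
        spectral_exponent=0.0, amplitude_scale=80, seed=13))
    return eeg, eog, emg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
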