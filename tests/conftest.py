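import numpy as np
import pytest

from heartframe.io import WORKING_FS, AudioSignal
from heartframe.synthetic import SynthParams, synth_heart_sound

FS = WORKING_FS


@pytest.fixture(scope="session")
def clean_pcg():
    """One clean 10 s synthetic heart sound at 60 bpm with its truth."""
    return synth_heart_sound(SynthParams(duration=10.0, heart_rate=60.0, seed=11))


@pytest.fixture(scope="session")
def noisy_pcg():
    """8 s heart sound with 10 dB additive noise and its ground truth."""
    return synth_heart_sound(SynthParams(duration=8.0, noise_snr_db=10.0, seed=12))


@pytest.fixture()
def tone():
    """100 Hz tone, 2 s at the working rate, amplitude 0.5."""
    t = np.arange(2 * FS) / FS
    return AudioSignal(0.5 * np.sin(2 * np.pi * 100 * t), FS, signal_id="tone")


@pytest.fixture(scope="session")
def frame_5s(clean_pcg):
    """A preprocessed-size 5 s frame from the clean fixture."""
    sig, _ = clean_pcg
    return sig.samples[: 5 * FS]
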