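import numpy as np
import pytest

from pcgseg import HeartSoundRecord, SynthParams, generate_record


@pytest.fixture(scope="session")
def clean_record_80bpm():
    """A 20 s synthetic record at 80 bpm with its ground-truth annotations."""
    return generate_record(SynthParams(hr_bpm=80.0, seed=7))


@pytest.fixture(scope="session")
def noiseless_record_60bpm():
    """A 20 s record at 60 bpm without background noise (exact waveform)."""
    return generate_record(SynthParams(hr_bpm=60.0, seed=1,
                                       background_snr_db=np.inf))


@pytest.fixture()
def sine_record():
    """1 s, 45 Hz unit sine at the 4000 Hz analysis rate."""
    t = np.arange(4000) / 4000.0
    return HeartSoundRecord(np.sin(2 * np.pi * 45.0 * t), 4000.0, "sine45")
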