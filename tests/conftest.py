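import numpy as np
import pytest

from snoredetect.audio_io import AudioSignal, FrameSpec, frame_energy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fs():
    return 16000


def make_signal(samples, fs=16000, cal=100.0):
    return AudioSignal(np.clip(np.asarray(samples, dtype=float), -1.0, 1.0), fs, cal)


@pytest.fixture
def make_track():
    """Build an EnergyTrack directly from a per-frame dB sequence (Fr = 66.67)."""

    def _make(db_values, cal=0.0):
        energies = 10.0 ** ((np.asarray(db_values, dtype=float) - cal) / 10.0)
        from snoredetect.audio_io import EnergyTrack

        return EnergyTrack(
            energies=energies, frame_length=960, hop_length=240, sample_rate=16000, calibration_offset_db=cal
        )

    return _make
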