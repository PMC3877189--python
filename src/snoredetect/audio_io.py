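"""Audio and label I/O, framing, and the calibrated dB intensity scale.

All intensities in this package are expressed on an SPL-like dB scale:
``10*log10(mean-square amplitude) + calibration_offset_db``.  The recording
chain that motivated this pipeline was calibrated to report snores between
roughly 20 and 80 dB; since no absolute calibration constant is available
for arbitrary recordings, the offset is a per-signal attribute (default
100 dB, which places a full-scale RMS signal at 100 dB and an RMS of 0.01
at 60 dB — the synthetic generator's reference snore level).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import resample_poly

#: dB floor applied to linear frame energies before the calibration offset,
#: so silent frames do not produce -inf.
SILENCE_FLOOR_DB = -100.0

DEFAULT_CALIBRATION_DB = 100.0


class AudioInputError(ValueError):
    """Raised for unreadable, empty, or otherwise invalid audio input."""


@dataclass
class AudioSignal:
    """Calibrated mono sample stream.

    Parameters
    ----------
    samples:
        1-D float array of amplitudes in [-1, 1].
    sample_rate:
        Sampling rate in Hz.
    calibration_offset_db:
        Offset added to ``10*log10(mean-square)`` to express intensity on
        the calibrated dB scale.
    """

    samples: np.ndarray
    sample_rate: int
    calibration_offset_db: float = DEFAULT_CALIBRATION_DB

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioInputError("AudioSignal expects a 1-D sample array")
        if self.samples.size < 1:
            raise AudioInputError("AudioSignal must contain at least one sample")
        if self.sample_rate <= 0:
            raise AudioInputError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def intensity_db(self) -> float:
        """Mean intensity of the whole signal on the calibrated dB scale."""
        ms = float(np.mean(self.samples**2))
        return 10.0 * math.log10(max(ms, 10.0 ** (SILENCE_FLOOR_DB / 10.0))) + self.calibration_offset_db


@dataclass(frozen=True)
class FrameSpec:
    """Analysis frame geometry (duration + overlap) and the derived frame rate."""

    frame_ms: float = 60.0
    overlap_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def hop_ms(self) -> float:
        return self.frame_ms * (1.0 - self.overlap_fraction)

    @property
    def frame_rate(self) -> float:
        """Frames per second (Fr)."""
        return 1000.0 / self.hop_ms

    def frame_length(self, sample_rate: int) -> int:
        return int(round(self.frame_ms * sample_rate / 1000.0))

    def hop_length(self, sample_rate: int) -> int:
        hop = int(round(self.frame_length(sample_rate) * (1.0 - self.overlap_fraction)))
        return max(hop, 1)


@dataclass
class EnergyTrack:
    """Per-frame energy sequence with linear and calibrated-dB views."""

    energies: np.ndarray  # linear mean-square energy per frame
    frame_length: int  # samples
    hop_length: int  # samples
    sample_rate: int
    calibration_offset_db: float = DEFAULT_CALIBRATION_DB

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.energies.size

    @property
    def frame_rate(self) -> float:
        """Frames per second (Fr)."""
        return self.sample_rate / self.hop_length

    @property
    def db(self) -> np.ndarray:
        """Calibrated dB view, floored at the silence floor."""
        floor = 10.0 ** (SILENCE_FLOOR_DB / 10.0)
        return 10.0 * np.log10(np.maximum(self.energies, floor)) + self.calibration_offset_db

    def frame_time_s(self, frame_index: np.ndarray | int) -> np.ndarray | float:
        """Center time (seconds) of a frame index."""
        return (np.asarray(frame_index) * self.hop_length + self.frame_length / 2.0) / self.sample_rate

    def frame_start_s(self, frame_index: int) -> float:
        return frame_index * self.hop_length / self.sample_rate

    def frame_end_s(self, frame_index: int) -> float:
        """End time of the (inclusive) frame index, i.e. start of frame + frame length."""
        return (frame_index * self.hop_length + self.frame_length) / self.sample_rate


@dataclass(frozen=True)
class LabeledEventRecord:
    """A manually (or synthetically) labeled acoustic event."""

    onset_s: float
    offset_s: float
    label: str  # "snore" or "nonsnore"

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_s < self.offset_s):
            raise ValueError(f"invalid interval [{self.onset_s}, {self.offset_s})")
        if self.label not in ("snore", "nonsnore"):
            raise ValueError(f"label must be 'snore' or 'nonsnore', got {self.label!r}")


def normalize_label(raw: str) -> str:
    """Map free-form label text onto the canonical {snore, nonsnore} pair."""
    text = str(raw).strip().lower().replace("-", "").replace("_", "").replace(" ", "")
    if text in ("snore", "snoring", "s"):
        return "snore"
    if text in ("nonsnore", "noise", "n", "notsnore"):
        return "nonsnore"
    raise ValueError(f"unrecognized event label {raw!r}")


def load_audio(
    path: str | Path,
    target_rate: int = 16000,
    calibration_offset_db: float = DEFAULT_CALIBRATION_DB,
) -> AudioSignal:
    """Read a PCM/float WAV file, take the first channel, resample to ``target_rate``.

    Integer PCM is scaled to [-1, 1]; resampling is polyphase anti-aliased;
    a file already at ``target_rate`` is passed through bit-identically.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise AudioInputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioInputError(f"empty audio file: {path}")
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if rate != target_rate:
        frac = Fraction(target_rate, int(rate))
        samples = resample_poly(samples, frac.numerator, frac.denominator)
    return AudioSignal(np.clip(samples, -1.0, 1.0), target_rate, calibration_offset_db)


def save_audio(path: str | Path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a WAV file (``subtype`` in {'float32', 'int16'})."""
    if subtype == "float32":
        wavfile.write(path, signal.sample_rate, signal.samples.astype(np.float32))
    elif subtype == "int16":
        scaled = np.clip(signal.samples, -1.0, 1.0) * 32767.0
        wavfile.write(path, signal.sample_rate, scaled.astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")


def frame_energy(signal: AudioSignal, spec: FrameSpec | None = None) -> EnergyTrack:
    """Short-time energy track: per-frame mean of squared samples.

    The number of frames is ``floor((N - frame_len)/hop) + 1``; a signal
    shorter than one frame is an input error.
    """
    spec = spec or FrameSpec()
    frame_len = spec.frame_length(signal.sample_rate)
    hop = spec.hop_length(signal.sample_rate)
    if signal.samples.size < frame_len:
        raise AudioInputError(
            f"signal ({signal.samples.size} samples) shorter than one frame ({frame_len})"
        )
    frames = sliding_window_view(signal.samples, frame_len)[::hop]
    energies = np.mean(frames**2, axis=1)
    return EnergyTrack(
        energies=energies,
        frame_length=frame_len,
        hop_length=hop,
        sample_rate=signal.sample_rate,
        calibration_offset_db=signal.calibration_offset_db,
    )


def read_labels(path: str | Path) -> list[LabeledEventRecord]:
    """Read an event-label CSV (columns onset_s, offset_s, label), sorted by onset."""
    df = pd.read_csv(path)
    required = {"onset_s", "offset_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label file {path} must have columns {sorted(required)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                LabeledEventRecord(
                    onset_s=float(row.onset_s),
                    offset_s=float(row.offset_s),
                    label=normalize_label(row.label),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed label row {i + 2} in {path}: {exc}") from exc
    records.sort(key=lambda r: r.onset_s)
    for a, b in zip(records, records[1:]):
        if b.onset_s < a.offset_s:
            warnings.warn(
                f"overlapping label intervals [{a.onset_s:.3f},{a.offset_s:.3f}) and "
                f"[{b.onset_s:.3f},{b.offset_s:.3f}) in {path}",
                stacklevel=2,
            )
    return records


def write_labels(path: str | Path, records: list[LabeledEventRecord]) -> None:
    """Write event labels as CSV (seconds, 1 ms precision), sorted by onset."""
    ordered = sorted(records, key=lambda r: r.onset_s)
    df = pd.DataFrame(
        {
            "onset_s": [round(r.onset_s, 3) for r in ordered],
            "offset_s": [round(r.offset_s, 3) for r in ordered],
            "label": [r.label for r in ordered],
        }
    )
    df.to_csv(path, index=False)


def db_from_linear(energy: np.ndarray | float, calibration_offset_db: float = 0.0) -> np.ndarray | float:
    """Convert linear mean-square energy to the calibrated dB scale."""
    floor = 10.0 ** (SILENCE_FLOOR_DB / 10.0)
    return 10.0 * np.log10(np.maximum(energy, floor)) + calibration_offset_db


def linear_from_db(db: np.ndarray | float, calibration_offset_db: float = 0.0) -> np.ndarray | float:
    """Inverse of :func:`db_from_linear` (above the silence floor)."""
    return 10.0 ** ((np.asarray(db, dtype=float) - calibration_offset_db) / 10.0)
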