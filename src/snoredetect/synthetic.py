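"""Synthetic whole-night sleep-audio generator with ground truth.

Real whole-night bedroom recordings of snoring are not publicly
distributable, so every stage of this package is exercised on synthetic
nights: quasi-periodic inspiratory snore surrogates (a glottal-like pulse
train mixed with noise, shaped by 2-3 vocal-tract-style resonances and a
rise-sustain-fall envelope), sporadic non-snore transients (clicks,
cough-like bursts with a sweeping spectrum, speech-like voiced streams with
moving formants), all over stationary pink background noise at a controlled
level.  Event timing follows a breathing-period schedule with jitter, and
the generator returns sample-accurate ground truth.

Default parameter ranges bracket what is reported for clinical populations:
event durations 0.2-3.5 s, intensities spanning 25-75 dB on the calibrated
scale, breathing periods of 2-8 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from snoredetect.audio_io import DEFAULT_CALIBRATION_DB, AudioSignal


@dataclass(frozen=True)
class GroundTruthEvent:
    onset_s: float
    offset_s: float
    label: str  # "snore" or "nonsnore"
    intensity_db: float  # programmed event intensity


@dataclass
class SnoreBlock:
    """A stretch of quasi-periodic snoring."""

    count: int = 100
    period_mean_s: float = 4.0
    period_jitter_s: float = 0.3
    duration_range_s: tuple[float, float] = (0.6, 1.4)
    intensity_range_db: tuple[float, float] = (55.0, 65.0)
    pitch_hz: float = 90.0
    resonances_hz: tuple[float, ...] = (450.0, 1200.0, 2200.0)

    def validate(self) -> None:
        if not (0.2 <= self.duration_range_s[0] <= self.duration_range_s[1] <= 3.5):
            raise ValueError("snore duration range must lie within [0.2, 3.5] s")
        if self.period_mean_s - self.period_jitter_s <= self.duration_range_s[1]:
            raise ValueError("breathing period must exceed the maximum event duration")


@dataclass
class NoiseEventSpec:
    """Sporadic non-snore events of one kind."""

    kind: str = "cough"  # click | cough | speechlike
    count: int = 10
    intensity_range_db: tuple[float, float] = (50.0, 65.0)


@dataclass
class NightSpec:
    """Recipe for one synthetic night."""

    duration_s: float = 600.0
    background_db: float = 35.0
    background_color: str = "pink"  # pink | white
    snore_blocks: list[SnoreBlock] = field(default_factory=lambda: [SnoreBlock()])
    noise_events: list[NoiseEventSpec] = field(default_factory=lambda: [NoiseEventSpec()])
    sample_rate: int = 16000
    calibration_offset_db: float = DEFAULT_CALIBRATION_DB
    seed: int = 0


def _target_rms(intensity_db: float, calibration_offset_db: float) -> float:
    return 10.0 ** ((intensity_db - calibration_offset_db) / 20.0)


def _scale_to_intensity(x: np.ndarray, intensity_db: float, calibration_offset_db: float) -> np.ndarray:
    rms = float(np.sqrt(np.mean(x**2)))
    if rms <= 0:
        return x
    return x * (_target_rms(intensity_db, calibration_offset_db) / rms)


def _resonator_coeffs(freq_hz: float, bw_hz: float, fs: int) -> tuple[np.ndarray, np.ndarray]:
    r = math.exp(-math.pi * bw_hz / fs)
    theta = 2.0 * math.pi * freq_hz / fs
    a = np.array([1.0, -2.0 * r * math.cos(theta), r * r])
    b = np.array([1.0 - r])
    return b, a


def _envelope(n: int, fs: int, rise_ms: float = 50.0, fall_ms: float = 80.0) -> np.ndarray:
    env = np.ones(n)
    rise = min(int(round(rise_ms * fs / 1000.0)), n // 2)
    fall = min(int(round(fall_ms * fs / 1000.0)), n // 2)
    if rise > 0:
        env[:rise] = 0.5 - 0.5 * np.cos(np.pi * np.arange(rise) / rise)
    if fall > 0:
        env[n - fall :] = 0.5 + 0.5 * np.cos(np.pi * np.arange(fall) / fall)
    return env


def generate_snore_event(
    duration_s: float,
    intensity_db: float,
    pitch_hz: float = 90.0,
    resonances_hz: tuple[float, ...] = (450.0, 1200.0, 2200.0),
    rng: np.random.Generator | None = None,
    fs: int = 16000,
    calibration_offset_db: float = DEFAULT_CALIBRATION_DB,
) -> np.ndarray:
    """One inspiratory snore surrogate.

    Excitation is a pulse train at the requested pitch mixed with white
    noise, filtered through resonances (formant-like poles, 150-250 Hz
    bandwidths) and shaped by a rise-sustain-fall amplitude envelope; the
    snippet is scaled so its mean-square level equals ``intensity_db`` on
    the calibrated scale.
    """
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * fs))
    period = max(2, int(round(fs / pitch_hz)))
    excitation = np.zeros(n)
    # ~1% pitch-period jitter: quasi-periodic but still strongly
    # autocorrelated at one period lag, as voiced biological sound is
    pos = 0
    while pos < n:
        excitation[pos] = 1.0
        pos += period + int(round(rng.normal(0.0, 0.01 * period)))
        if pos <= 0:
            break
    # turbulent-noise component at ~30% of the pulse-train RMS: voiced
    # enough that the waveform stays periodic at one pitch-period lag
    excitation += 0.3 / math.sqrt(period) * rng.standard_normal(n)
    out = excitation
    for i, f in enumerate(resonances_hz):
        b, a = _resonator_coeffs(f, 150.0 + 50.0 * i, fs)
        out = lfilter(b, a, out)
    out *= _envelope(n, fs)
    return _scale_to_intensity(out, intensity_db, calibration_offset_db)


def _chunked_filter(excitation: np.ndarray, freqs: np.ndarray, bw_hz: float, fs: int, chunk_ms: float = 40.0) -> np.ndarray:
    """Filter in short chunks with a per-chunk resonance frequency (non-stationary spectrum)."""
    n = excitation.size
    chunk = max(1, int(round(chunk_ms * fs / 1000.0)))
    out = np.zeros(n)
    zi = None
    for i, start in enumerate(range(0, n, chunk)):
        f = freqs[min(i, freqs.size - 1)]
        b, a = _resonator_coeffs(float(f), bw_hz, fs)
        seg = excitation[start : start + chunk]
        if zi is None:
            zi = np.zeros(max(len(a), len(b)) - 1)
        out[start : start + chunk], zi = lfilter(b, a, seg, zi=zi)
    return out


def generate_noise_event(
    kind: str,
    intensity_db: float,
    rng: np.random.Generator | None = None,
    fs: int = 16000,
    calibration_offset_db: float = DEFAULT_CALIBRATION_DB,
    duration_s: float | None = None,
) -> np.ndarray:
    """A non-snore transient: ``click``, ``cough``, or ``speechlike``.

    Clicks are sub-100 ms broadband transients (removed downstream by the
    duration test); coughs are 0.3-0.8 s bursts whose dominant resonance
    sweeps downward (falling spectral tilt, non-stationary spectrum);
    speech-like events are voiced streams with randomly moving formants.
    """
    rng = rng or np.random.default_rng()
    if kind == "click":
        dur = duration_s if duration_s is not None else rng.uniform(0.01, 0.08)
        n = int(round(dur * fs))
        x = rng.standard_normal(n) * np.exp(-np.arange(n) / (0.2 * n + 1))
    elif kind == "cough":
        dur = duration_s if duration_s is not None else rng.uniform(0.3, 0.8)
        n = int(round(dur * fs))
        n_chunks = n // int(0.04 * fs) + 1
        sweep = np.linspace(rng.uniform(2500, 3500), rng.uniform(300, 600), n_chunks)
        x = _chunked_filter(rng.standard_normal(n), sweep, 400.0, fs)
        x *= np.exp(-np.arange(n) / (0.45 * n + 1)) * _envelope(n, fs, rise_ms=15.0, fall_ms=60.0)
    elif kind == "speechlike":
        dur = duration_s if duration_s is not None else rng.uniform(0.5, 2.5)
        n = int(round(dur * fs))
        period = int(round(fs / rng.uniform(100.0, 180.0)))
        excitation = np.zeros(n)
        excitation[::period] = 1.0
        excitation += 0.1 * rng.standard_normal(n)
        n_chunks = n // int(0.04 * fs) + 1
        # two formant tracks wandering as in running speech
        f1 = np.clip(np.cumsum(rng.normal(0, 60, n_chunks)) + rng.uniform(350, 750), 250, 1000)
        f2 = np.clip(np.cumsum(rng.normal(0, 120, n_chunks)) + rng.uniform(1100, 2000), 900, 2800)
        x = _chunked_filter(excitation, f1, 120.0, fs) + _chunked_filter(excitation, f2, 180.0, fs)
        x *= _envelope(n, fs, rise_ms=40.0, fall_ms=60.0)
    else:
        raise ValueError(f"unknown noise-event kind {kind!r}")
    return _scale_to_intensity(x, intensity_db, calibration_offset_db)


def _background(n: int, color: str, level_db: float, calibration_offset_db: float, rng: np.random.Generator, fs: int = 16000) -> np.ndarray:
    white = rng.standard_normal(n)
    if color == "white":
        noise = white
    elif color == "pink":
        # 1/f power above a 20 Hz corner; recording chains high-pass the
        # infrasound region, so the spectrum is flat below the corner
        spectrum = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        f = np.maximum(f, 20.0)
        noise = np.fft.irfft(spectrum / np.sqrt(f), n)
    else:
        raise ValueError(f"unknown background color {color!r}")
    return _scale_to_intensity(noise, level_db, calibration_offset_db)


def generate_corpus(
    n_recordings: int = 10,
    snores_per_recording: int = 50,
    noises_per_recording: int = 50,
    intensity_range_db: tuple[float, float] = (45.0, 70.0),
    seed: int = 0,
) -> list[tuple[AudioSignal, list[tuple[float, float, str]]]]:
    """A labeled multi-recording corpus for classifier design.

    Each recording mimics a different subject: its own breathing period,
    snore pitch and resonances, with snore intensities drawn from
    ``intensity_range_db`` and non-snore events split between cough-like
    and speech-like kinds (both long enough to survive the duration test).
    Returns (signal, [(onset_s, offset_s, label), ...]) pairs.
    """
    master = np.random.default_rng(seed)
    corpus = []
    for _ in range(n_recordings):
        period = float(master.uniform(2.8, 6.0))
        pitch = float(master.uniform(70.0, 130.0))
        resonances = (
            float(master.uniform(350, 550)),
            float(master.uniform(1000, 1500)),
            float(master.uniform(1900, 2500)),
        )
        block = SnoreBlock(
            count=snores_per_recording,
            period_mean_s=period,
            period_jitter_s=0.1 * period,
            duration_range_s=(0.5, min(1.6, period - 1.0)),
            intensity_range_db=intensity_range_db,
            pitch_hz=pitch,
            resonances_hz=resonances,
        )
        half = noises_per_recording // 2
        noises = [
            NoiseEventSpec("cough", half, intensity_range_db),
            NoiseEventSpec("speechlike", noises_per_recording - half, intensity_range_db),
        ]
        duration = snores_per_recording * period + noises_per_recording * 3.0 + 60.0
        spec = NightSpec(
            duration_s=duration,
            snore_blocks=[block],
            noise_events=noises,
            seed=int(master.integers(2**31 - 1)),
        )
        signal, truth = generate_night(spec)
        corpus.append((signal, [(t.onset_s, t.offset_s, t.label) for t in truth]))
    return corpus


class PackingError(RuntimeError):
    """Raised when the requested events cannot be placed without overlap."""


def generate_night(spec: NightSpec) -> tuple[AudioSignal, list[GroundTruthEvent]]:
    """Render a synthetic night and its ground-truth event list.

    Snore blocks are laid out sequentially along the night, events within a
    block following the block's breathing period with Gaussian jitter.
    Noise events are placed uniformly at random in the remaining free time;
    overlaps are rejected.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    audio = _background(n, spec.background_color, spec.background_db, spec.calibration_offset_db, rng, fs)

    truth: list[GroundTruthEvent] = []
    intervals: list[tuple[float, float]] = []  # occupied [onset, offset)

    for block in spec.snore_blocks:
        block.validate()

    total_block_s = sum(b.count * b.period_mean_s for b in spec.snore_blocks)
    if total_block_s > spec.duration_s:
        raise PackingError(
            f"snore schedule needs {total_block_s:.0f} s but the night lasts {spec.duration_s:.0f} s"
        )

    # snore blocks laid end to end, spare time split evenly between them
    spare = (spec.duration_s - total_block_s) / max(1, len(spec.snore_blocks))
    t = 1.0  # leave the first second for the noise-template window
    for block in spec.snore_blocks:
        for _ in range(block.count):
            duration = rng.uniform(*block.duration_range_s)
            intensity = rng.uniform(*block.intensity_range_db)
            onset = t
            offset = onset + duration
            if offset > spec.duration_s:
                raise PackingError("snore schedule exceeds the night duration")
            snippet = generate_snore_event(
                duration, intensity, block.pitch_hz, block.resonances_hz, rng, fs, spec.calibration_offset_db
            )
            i0 = int(round(onset * fs))
            audio[i0 : i0 + snippet.size] += snippet
            truth.append(GroundTruthEvent(onset, onset + snippet.size / fs, "snore", intensity))
            intervals.append((onset - 0.1, onset + snippet.size / fs + 0.1))
            period = block.period_mean_s + rng.normal(0.0, block.period_jitter_s)
            t = onset + max(period, duration + 0.3)
        t += spare

    def overlaps(a: float, b: float) -> bool:
        return any(a < hi and b > lo for lo, hi in intervals)

    for noise_spec in spec.noise_events:
        for _ in range(noise_spec.count):
            intensity = rng.uniform(*noise_spec.intensity_range_db)
            snippet = generate_noise_event(noise_spec.kind, intensity, rng, fs, spec.calibration_offset_db)
            dur = snippet.size / fs
            placed = False
            for _attempt in range(200):
                onset = rng.uniform(1.0, spec.duration_s - dur - 0.1)
                if not overlaps(onset - 0.3, onset + dur + 0.3):
                    placed = True
                    break
            if not placed:
                raise PackingError(
                    f"could not place a {noise_spec.kind!r} event without overlap after 200 tries"
                )
            i0 = int(round(onset * fs))
            audio[i0 : i0 + snippet.size] += snippet
            truth.append(GroundTruthEvent(onset, onset + snippet.size / fs, "nonsnore", intensity))
            intervals.append((onset - 0.1, onset + dur + 0.1))

    truth.sort(key=lambda ev: ev.onset_s)
    peak = np.max(np.abs(audio))
    if peak > 1.0:  # keep within [-1, 1] without changing relative levels
        audio /= peak
    return AudioSignal(audio, fs, spec.calibration_offset_db), truth
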