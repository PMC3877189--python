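"""Adaptive Wiener-type spectral subtraction for background-noise suppression.

A noise power-spectrum template is initialised from the lowest-energy
40 ms frame of the first 10 s of the recording and then tracked during
processing by exponential smoothing on frames classified as background
(energy below a running low-energy quantile).  Each analysis frame is
attenuated per frequency bin by a Wiener gain ``G = xi/(1+xi)`` where the
a-priori SNR ``xi`` follows the decision-directed estimate (smoothed across
frequency, with over-subtraction of the noise estimate); the amplitude gain
is clamped to the range [-25 dB, 0 dB], so the filter can only attenuate
and never by more than 25 dB — this bounds the distortion on low-SNR
events.  Frames are Hann-windowed at 50% overlap and reconstructed by
overlap-add with the original phase.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from snoredetect.audio_io import AudioSignal, EnergyTrack, db_from_linear


@dataclass
class NoiseTemplate:
    """Background-noise magnitude-spectrum estimate for one frame geometry."""

    magnitude: np.ndarray  # linear magnitude per rfft bin
    frame_ms: float = 40.0
    update_factor: float = 0.98  # exponential smoothing weight on the old template

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if np.any(self.magnitude < 0):
            raise ValueError("noise template magnitudes must be non-negative")


def _frame_starts(n: int, frame_len: int, hop: int) -> range:
    if n < frame_len:
        return range(0)
    return range(0, n - frame_len + 1, hop)


def init_noise_template(
    signal: AudioSignal,
    window_s: float = 10.0,
    frame_ms: float = 40.0,
    update_factor: float = 0.98,
) -> NoiseTemplate:
    """Estimate the initial noise template from the quietest frame of the signal head.

    The template is the magnitude spectrum (Hann-windowed rfft) of the
    minimum-energy ``frame_ms`` frame within the first ``window_s`` seconds.
    """
    fs = signal.sample_rate
    frame_len = int(round(frame_ms * fs / 1000.0))
    hop = frame_len // 2
    head = signal.samples[: int(round(window_s * fs))]
    if head.size < int(round(window_s * fs)):
        warnings.warn(
            f"signal shorter than {window_s} s; noise template estimated from whole signal",
            stacklevel=2,
        )
    if head.size < frame_len:
        head = np.pad(head, (0, frame_len - head.size))
    window = np.hanning(frame_len)
    best_energy = np.inf
    best_start = 0
    for start in _frame_starts(head.size, frame_len, hop):
        e = float(np.mean(head[start : start + frame_len] ** 2))
        if e < best_energy:
            best_energy = e
            best_start = start
    spectrum = np.abs(np.fft.rfft(head[best_start : best_start + frame_len] * window))
    return NoiseTemplate(magnitude=spectrum, frame_ms=frame_ms, update_factor=update_factor)


def suppress_noise(
    signal: AudioSignal,
    template: NoiseTemplate,
    clamp_db: float = -25.0,
    background_percentile: float = 20.0,
    trailing_window_s: float = 10.0,
    over_subtract: float = 4.0,
    freq_smooth_bins: int = 9,
    return_gains: bool = False,
) -> AudioSignal | tuple[AudioSignal, np.ndarray]:
    """Frame-by-frame spectral subtraction with a clamped Wiener gain.

    Parameters
    ----------
    clamp_db:
        Lower clamp of the per-bin amplitude gain in dB (upper clamp is 0 dB).
    background_percentile:
        Frames whose energy falls below this percentile of the trailing
        ``trailing_window_s`` seconds of frame energies are treated as
        background and update the noise template.
    over_subtract:
        Over-subtraction factor on the noise-power estimate; values above 1
        push the ordinary per-bin fluctuations of stationary background
        below the gain floor instead of letting them leak through.
    freq_smooth_bins:
        Width of the moving average applied to the power/noise ratio across
        frequency before the gain rule.  Single-bin periodogram values of
        stationary noise are exponentially distributed, so without this
        smoothing a few random bins per frame always leak through as
        "musical noise" spikes.
    return_gains:
        If True also return the (n_frames, n_bins) matrix of applied gains
        in dB, for instrumentation.
    """
    fs = signal.sample_rate
    frame_len = int(round(template.frame_ms * fs / 1000.0))
    hop = frame_len // 2
    x = signal.samples
    n = x.size
    if n < frame_len:
        out = signal.samples.copy()
        gains = np.zeros((0, frame_len // 2 + 1))
        result = AudioSignal(out, fs, signal.calibration_offset_db)
        return (result, gains) if return_gains else result

    window = np.hanning(frame_len)
    # pad so every real sample gets full analysis-window coverage; the
    # overlap-add is normalized by the window-square sum afterwards
    pad = frame_len
    x = np.pad(x, (pad, pad))
    n_padded = x.size
    n_frames = (n_padded - frame_len) // hop + 1
    gain_floor = 10.0 ** (clamp_db / 20.0)

    noise_mag = template.magnitude.astype(np.float64).copy()
    alpha = template.update_factor
    trailing = deque(maxlen=max(1, int(round(trailing_window_s * fs / hop))))

    out = np.zeros(n_padded)
    wsum = np.zeros(n_padded)
    gains_db = np.empty((n_frames, frame_len // 2 + 1)) if return_gains else None

    noise_power = noise_mag**2
    # warm-up: adapt the template over the first trailing window before any
    # output is produced.  The single-frame initial estimate has large
    # per-bin variance, and converging it on-line would leave the first few
    # seconds of output under-suppressed (a spurious event at t=0).
    warm_frames = min(n_frames, max(1, int(round(trailing_window_s * fs / hop))))
    warm_trailing: deque = deque(maxlen=warm_frames)
    for i in range(warm_frames):
        frame = x[i * hop : i * hop + frame_len]
        power = np.abs(np.fft.rfft(frame * window)) ** 2
        energy = float(np.mean(frame**2))
        warm_trailing.append(energy)
        if energy <= np.percentile(warm_trailing, background_percentile):
            noise_power = alpha * noise_power + (1.0 - alpha) * power

    # decision-directed a-priori SNR smoothing suppresses "musical noise":
    # without it the residual background is spiky and floods the event
    # detector's energy histogram with spurious crossings
    dd_alpha = 0.96
    prev_clean_power = None
    for i in range(n_frames):
        start = i * hop
        frame = x[start : start + frame_len]
        fw = frame * window
        spec = np.fft.rfft(fw)
        power = np.abs(spec) ** 2
        np_safe = np.maximum(noise_power, 1e-300)
        ratio = power / np_safe
        if freq_smooth_bins > 1:
            ratio = np.convolve(ratio, np.ones(freq_smooth_bins) / freq_smooth_bins, mode="same")
        post_snr = np.maximum(ratio - over_subtract, 0.0)
        if prev_clean_power is None:
            prior_snr = post_snr
        else:
            prior_snr = dd_alpha * prev_clean_power / np_safe + (1.0 - dd_alpha) * post_snr
        gain = prior_snr / (1.0 + prior_snr)
        gain = np.clip(gain, gain_floor, 1.0)
        prev_clean_power = (gain**2) * power
        if gains_db is not None:
            gains_db[i] = 20.0 * np.log10(gain)
        y = np.fft.irfft(spec * gain, frame_len)
        out[start : start + frame_len] += y * window
        wsum[start : start + frame_len] += window**2

        # track background: frames quiet relative to the trailing window
        energy = float(np.mean(frame**2))
        trailing.append(energy)
        if energy <= np.percentile(trailing, background_percentile):
            # smoothing in the power domain: a magnitude-domain average
            # underestimates noise power (Rayleigh bias)
            noise_power = alpha * noise_power + (1.0 - alpha) * power

    covered = wsum > 1e-8
    out[covered] /= wsum[covered]
    out[~covered] = x[~covered]
    out = out[pad : pad + n]
    template.magnitude = np.sqrt(noise_power)
    result = AudioSignal(np.clip(out, -1.0, 1.0), fs, signal.calibration_offset_db)
    return (result, gains_db) if return_gains else result


def event_snr(
    track: EnergyTrack,
    start_frame: int,
    end_frame: int,
    other_events: list[tuple[int, int]] | None = None,
    context_s: float = 5.0,
) -> float:
    """Event SNR in dB: event mean dB energy minus surrounding background dB.

    Background is estimated from non-event frames within ``context_s``
    seconds on each side of the event, excluding frames covered by
    ``other_events`` (list of inclusive frame-index pairs).  Returns NaN when
    no background frame is available.
    """
    n = track.n_frames
    if not (0 <= start_frame <= end_frame < n):
        raise ValueError("event lies outside the energy track")
    context = int(round(context_s * track.frame_rate))
    lo = max(0, start_frame - context)
    hi = min(n, end_frame + 1 + context)
    mask = np.zeros(n, dtype=bool)
    mask[lo:hi] = True
    mask[start_frame : end_frame + 1] = False
    for a, b in other_events or []:
        mask[max(0, a) : min(n, b + 1)] = False
    if not mask.any():
        return float("nan")
    event_db = float(
        db_from_linear(np.mean(track.energies[start_frame : end_frame + 1]), track.calibration_offset_db)
    )
    background_db = float(db_from_linear(np.mean(track.energies[mask]), track.calibration_offset_db))
    return event_db - background_db
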