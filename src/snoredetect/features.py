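"""The 127-slot per-event feature pool.

Six categories mirror the time/spectral taxonomy used for ambient snore
classification:

* ``Ta`` (10) — inter-event periodicity: breathing-rhythm period and
  intensity from the autocorrelation of a logistic-transformed energy
  context (±12 s around the event), and the relative energy prior to the
  event (E_P).
* ``Tb`` (4) — duration and sample scattering.
* ``Tc`` (11) — energy: intensity, SNR, and the shape of the energy
  envelope over time.
* ``Sa`` (68) — spectral parameterization: LPC, MFCC, sub-band energy
  distribution and spectral-shape scalars with their first four moments
  across frames.
* ``Sb`` (10) — bio-characteristic frequencies: formants, pitch and
  pitch-related measures.
* ``Sc`` (24) — spectral dynamics: flux, frame-to-frame correlation,
  centroid velocity and sub-band trajectories (snore spectra are more
  stationary than most other bedroom noises).

Slots that cannot be computed (e.g. pitch of an unvoiced event, variance
moments of a single-frame event) are flagged as missing (NaN) and imputed
from training medians at classification time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct
from scipy.signal import find_peaks

from snoredetect.audio_io import AudioSignal, EnergyTrack
from snoredetect.event_detection import AudioEvent

# ---------------------------------------------------------------------------
# manifest

CATEGORY_SIZES = {"Ta": 10, "Tb": 4, "Tc": 11, "Sa": 68, "Sb": 10, "Sc": 24}

_N_LPC = 12
_N_MFCC = 13
_N_SUBBANDS = 8
_MOMENTS = ("mean", "var", "skew", "kurt")


def _manifest() -> list[tuple[str, str]]:
    names: list[tuple[str, str]] = []
    # Ta — periodicity
    for side in ("left", "right"):
        names.append((f"Ta_period_{side}", "rhythm period tau_p (s)"))
    for side in ("left", "right"):
        names.append((f"Ta_peak_{side}", "first autocorrelation peak R(tau_p)/R0"))
    for side in ("left", "right"):
        names.append((f"Ta_area_{side}", "normalized squared area below the R(0)->R(tau_p) chord"))
    for side in ("left", "right"):
        names.append((f"Ta_ri_{side}", "period intensity R_I = R(tau_p)*Area"))
    names.append(("Ta_ri_combined", "period intensity on the full +/-12 s context"))
    names.append(("Ta_ep", "relative energy prior to event E_P"))
    # Tb — duration
    names += [
        ("Tb_duration", "event duration (s)"),
        ("Tb_duration95", "95% energy duration (s)"),
        ("Tb_duration_ratio", "95% energy duration / total duration"),
        ("Tb_time_scatter", "energy-weighted std of time within the event (normalized)"),
    ]
    # Tc — energy
    names += [
        ("Tc_intensity", "mean event intensity (dB)"),
        ("Tc_peak", "peak frame intensity (dB)"),
        ("Tc_snr", "event SNR (dB)"),
        ("Tc_rise_time", "normalized time from onset to envelope peak"),
        ("Tc_fall_time", "normalized time from envelope peak to offset"),
        ("Tc_env_centroid", "normalized energy-weighted time centroid"),
        ("Tc_env_skew", "skewness of the energy-over-time shape"),
        ("Tc_env_kurt", "kurtosis of the energy-over-time shape"),
        ("Tc_crest", "peak-to-mean energy ratio (dB)"),
        ("Tc_mod_depth", "envelope modulation depth (max-min)/(max+min)"),
        ("Tc_energy_fill", "mean/peak linear envelope (fill factor)"),
    ]
    # Sa — spectral parameterization
    names += [(f"Sa_lpc_mean_{i+1}", f"frame-mean LPC coefficient a{i+1}") for i in range(_N_LPC)]
    names += [(f"Sa_mfcc_mean_{i+1}", f"frame-mean MFCC c{i+1}") for i in range(_N_MFCC)]
    names += [(f"Sa_subband_mean_{i+1}", f"frame-mean energy fraction, band {i+1}/8 of 0-8 kHz") for i in range(_N_SUBBANDS)]
    names += [(f"Sa_mfcc_std_{i+1}", f"frame-std MFCC c{i+1}") for i in range(_N_MFCC)]
    names += [(f"Sa_subband_std_{i+1}", f"frame-std energy fraction, band {i+1}/8") for i in range(_N_SUBBANDS)]
    for scalar in ("centroid", "bandwidth", "rolloff"):
        names += [(f"Sa_{scalar}_{m}", f"spectral {scalar}: {m} over frames") for m in _MOMENTS]
    names += [("Sa_flatness_mean", "frame-mean spectral flatness"), ("Sa_flatness_std", "frame-std spectral flatness")]
    # Sb — bio-characteristic frequencies
    names += [
        ("Sb_formant1", "first formant frequency (Hz)"),
        ("Sb_formant2", "second formant frequency (Hz)"),
        ("Sb_formant3", "third formant frequency (Hz)"),
        ("Sb_formant1_bw", "first formant bandwidth (Hz)"),
        ("Sb_pitch", "median pitch (Hz), autocorrelation method, 30-400 Hz"),
        ("Sb_voiced_fraction", "fraction of voiced frames"),
        ("Sb_pitch_stability", "pitch std/mean over voiced frames"),
        ("Sb_jitter", "mean relative pitch change between voiced frames"),
        ("Sb_harmonicity", "mean voiced autocorrelation peak height"),
        ("Sb_pitch_present", "1 if any voiced frame else 0"),
    ]
    # Sc — spectral dynamics
    names += [(f"Sc_flux_{m}", f"spectral flux: {m} over frames") for m in ("mean", "std", "max", "skew", "kurt")]
    names += [(f"Sc_corr_{m}", f"frame-to-frame spectral correlation: {m}") for m in ("mean", "std", "min", "median")]
    names += [(f"Sc_centroid_vel_{m}", f"spectral centroid velocity: {m}") for m in ("meanabs", "std", "max")]
    names += [(f"Sc_subband_var_{i+1}", f"trajectory variance of sub-band fraction {i+1}/8") for i in range(_N_SUBBANDS)]
    names += [
        ("Sc_flux_median", "median spectral flux"),
        ("Sc_bandwidth_vel_meanabs", "spectral bandwidth velocity: mean abs"),
        ("Sc_bandwidth_vel_std", "spectral bandwidth velocity: std"),
        ("Sc_rolloff_vel_meanabs", "spectral rolloff velocity: mean abs"),
    ]
    return names


_MANIFEST = _manifest()
FEATURE_NAMES: list[str] = [n for n, _ in _MANIFEST]
assert len(FEATURE_NAMES) == 127


def feature_manifest() -> list[dict[str, str]]:
    """Slot-by-slot documentation of the feature pool."""
    return [
        {"name": name, "category": name.split("_")[0], "description": desc}
        for name, desc in _MANIFEST
    ]


@dataclass
class FeatureVector:
    """Named 127-slot feature record for one event (NaN = missing)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if list(self.values.keys()) != FEATURE_NAMES:
            raise ValueError("FeatureVector must contain exactly the 127 manifest slots, in order")

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)

    def missing(self) -> list[str]:
        return [n for n, v in self.values.items() if not np.isfinite(v)]


# ---------------------------------------------------------------------------
# small numerics


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, kurtosis); higher moments NaN for n < 2 or zero spread."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return (math.nan,) * 4
    mean = float(np.mean(x))
    if x.size < 2:
        return mean, math.nan, math.nan, math.nan
    var = float(np.var(x))
    if var <= 0:
        return mean, 0.0, 0.0, 0.0
    z = (x - mean) / math.sqrt(var)
    return mean, var, float(np.mean(z**3)), float(np.mean(z**4))


def _weighted_shape(weights: np.ndarray) -> tuple[float, float, float]:
    """(normalized centroid, skewness, kurtosis) of time treated as a
    distribution with the (non-negative) weights."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0 or w.size < 2:
        return math.nan, math.nan, math.nan
    t = np.arange(w.size, dtype=float)
    mu = float(np.sum(t * w) / total)
    var = float(np.sum((t - mu) ** 2 * w) / total)
    if var <= 0:
        return mu / (w.size - 1), 0.0, 0.0
    sd = math.sqrt(var)
    skew = float(np.sum(((t - mu) / sd) ** 3 * w) / total)
    kurt = float(np.sum(((t - mu) / sd) ** 4 * w) / total)
    return mu / (w.size - 1), skew, kurt


def _frames(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    if x.size < frame_len:
        return x[np.newaxis, :] if x.size else np.zeros((0, frame_len))
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[np.newaxis, :] + hop * np.arange(n_frames)[:, np.newaxis]
    return x[idx]


def levinson_lpc(x: np.ndarray, order: int) -> np.ndarray:
    """LPC coefficients a1..a_order by the autocorrelation (Levinson-Durbin) method."""
    x = np.asarray(x, dtype=float)
    if x.size <= order:
        return np.full(order, np.nan)
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    if r[0] <= 0:
        return np.full(order, np.nan)
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + np.dot(a[1:i], r[i - 1 : 0 : -1])
        k = -acc / err
        a_prev = a.copy()
        for j in range(1, i):  # a_new[j] = a[j] + k*a[i-j]
            a[j] = a_prev[j] + k * a_prev[i - j]
        a[i] = k
        err *= 1.0 - k * k
        if err <= 0:
            break
    return a[1:]


def _mel_filterbank(n_filters: int, n_fft: int, fs: int, f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    f_hi = f_hi or fs / 2.0
    mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    pts = imel(np.linspace(mel(f_lo), mel(f_hi), n_filters + 2))
    bins = np.floor((n_fft + 1) * pts / fs).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        lo, ce, hi = bins[i], bins[i + 1], bins[i + 2]
        if ce > lo:
            fb[i, lo:ce] = (np.arange(lo, ce) - lo) / (ce - lo)
        if hi > ce:
            fb[i, ce:hi] = (hi - np.arange(ce, hi)) / (hi - ce)
    return fb


# ---------------------------------------------------------------------------
# periodicity (Ta)


@dataclass
class PeriodicityContext:
    """Autocorrelation analysis of one logistic-energy context segment."""

    tau_p: float = math.nan  # s
    peak: float = math.nan  # R(tau_p) / R0
    area: float = math.nan
    ri: float = math.nan


def logistic_energy(db_segment: np.ndarray, mu: float | None = None, s: float | None = None) -> np.ndarray:
    """Logistic transform of a dB energy segment onto (0, 1).

    Defaults center the sigmoid midway between the 10th and 90th
    percentiles with slope scale an eighth of that span (floored at 1 dB).
    Snoring occupies a minority of the time, so a centre between the
    background and event levels (rather than at the median, which sits
    inside the background mode) renders a snore/silence alternation nearly
    binary and emphasizes the breathing rhythm over intensity.
    """
    db_segment = np.asarray(db_segment, dtype=float)
    if db_segment.size == 0:
        raise ValueError("empty energy segment")
    p10, p90 = np.percentile(db_segment, [10, 90])
    if mu is None:
        mu = 0.5 * (p10 + p90)
    if s is None:
        s = max((p90 - p10) / 8.0, 1.0)
    return 1.0 / (1.0 + np.exp(-(db_segment - mu) / s))


def _autocorr_context(
    db_segment: np.ndarray,
    frame_rate: float,
    lag_range_s: tuple[float, float] = (1.0, 10.0),
    smooth: int = 5,
) -> PeriodicityContext:
    x = logistic_energy(db_segment)
    x = x - x.mean()
    n = x.size
    if n < int(lag_range_s[0] * frame_rate) + 2:
        return PeriodicityContext()
    r = np.correlate(x, x, mode="full")[n - 1 :]
    if r[0] <= 0:
        return PeriodicityContext()
    r = r / r[0]
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        r = np.convolve(r, kernel, mode="same")
        r = r / r[0] if r[0] > 0 else r
    lo = int(round(lag_range_s[0] * frame_rate))
    hi = min(int(round(lag_range_s[1] * frame_rate)), n - 1)
    if hi <= lo:
        return PeriodicityContext()
    # the rhythm peak must stand clear of the small ripples a noisy
    # autocorrelation always carries; otherwise the "first peak" latches
    # onto a ripple at a short lag instead of the breathing period
    peaks, _ = find_peaks(r[: hi + 1], prominence=0.1, height=0.05)
    peaks = peaks[(peaks >= lo) & (peaks <= hi)]
    if peaks.size == 0:
        return PeriodicityContext()
    p = int(peaks[0])
    tau_p = p / frame_rate
    peak_val = float(r[p])
    # chord a*tau + 1 from R(0)=1 to R(tau_p)
    taus = np.arange(p + 1) / frame_rate
    a = (peak_val - 1.0) / tau_p
    line = a * taus + 1.0
    area = float(np.trapezoid((r[: p + 1] - line) ** 2, taus) / tau_p)
    return PeriodicityContext(tau_p=tau_p, peak=peak_val, area=area, ri=peak_val * area)


def periodicity_features(
    track: EnergyTrack,
    event: AudioEvent,
    context_s: float = 12.0,
    lag_range_s: tuple[float, float] = (1.0, 10.0),
) -> dict[str, float]:
    """Ta_* autocorrelation slots from the left/right ±``context_s`` contexts.

    The left context spans from ``context_s`` before the event to its end
    (event aligned at the right edge); the right context from the event
    start to ``context_s`` after it; the combined measure uses the full
    two-sided context.  Contexts are truncated at recording edges.
    """
    fr = track.frame_rate
    ctx = int(round(context_s * fr))
    db = track.db
    lo = max(0, event.start_frame - ctx)
    hi = min(track.n_frames, event.end_frame + 1 + ctx)
    left = _autocorr_context(db[lo : event.end_frame + 1], fr, lag_range_s)
    right = _autocorr_context(db[event.start_frame : hi], fr, lag_range_s)
    both = _autocorr_context(db[lo:hi], fr, lag_range_s)
    return {
        "Ta_period_left": left.tau_p,
        "Ta_period_right": right.tau_p,
        "Ta_peak_left": left.peak,
        "Ta_peak_right": right.peak,
        "Ta_area_left": left.area,
        "Ta_area_right": right.area,
        "Ta_ri_left": left.ri,
        "Ta_ri_right": right.ri,
        "Ta_ri_combined": both.ri,
    }


def relative_prior_energy(track: EnergyTrack, event: AudioEvent, window_s: float = 10.0) -> float:
    """E_P: linear energy in the ``window_s`` seconds before the event over
    the event's own energy; a truncated prior window is scaled up
    proportionally."""
    w = int(round(window_s * track.frame_rate))
    lo = max(0, event.start_frame - w)
    prior = track.energies[lo : event.start_frame]
    denom = float(np.sum(track.energies[event.start_frame : event.end_frame + 1]))
    if denom <= 0:
        raise ValueError("event has zero energy")
    total = float(np.sum(prior))
    if prior.size == 0:
        return 0.0
    if prior.size < w:  # proportional renormalization at the recording edge
        total *= w / prior.size
    return total / denom


# ---------------------------------------------------------------------------
# duration (Tb) and energy (Tc)


def duration_features(signal: AudioSignal, event: AudioEvent) -> dict[str, float]:
    fs = signal.sample_rate
    seg = signal.samples[int(round(event.start_s * fs)) : int(round(event.end_s * fs))]
    duration = event.end_s - event.start_s
    out = {
        "Tb_duration": duration,
        "Tb_duration95": math.nan,
        "Tb_duration_ratio": math.nan,
        "Tb_time_scatter": math.nan,
    }
    energy = seg**2
    total = energy.sum()
    if total > 0 and seg.size > 1:
        cum = np.cumsum(energy) / total
        t_lo = float(np.searchsorted(cum, 0.025)) / fs
        t_hi = float(np.searchsorted(cum, 0.975)) / fs
        out["Tb_duration95"] = t_hi - t_lo
        out["Tb_duration_ratio"] = (t_hi - t_lo) / duration if duration > 0 else math.nan
        t = np.arange(seg.size) / fs
        mu = float(np.sum(t * energy) / total)
        out["Tb_time_scatter"] = math.sqrt(float(np.sum((t - mu) ** 2 * energy) / total)) / max(duration, 1e-9)
    return out


def energy_features(track: EnergyTrack, event: AudioEvent) -> dict[str, float]:
    env = track.energies[event.start_frame : event.end_frame + 1]
    out = {name: math.nan for name in FEATURE_NAMES if name.startswith("Tc_")}
    out["Tc_intensity"] = event.intensity_db
    out["Tc_peak"] = event.peak_db
    out["Tc_snr"] = event.snr_db
    if env.size == 0 or env.max() <= 0:
        return out
    peak_idx = int(np.argmax(env))
    n = env.size
    out["Tc_rise_time"] = peak_idx / max(n - 1, 1)
    out["Tc_fall_time"] = (n - 1 - peak_idx) / max(n - 1, 1)
    centroid, skew, kurt = _weighted_shape(env)
    out["Tc_env_centroid"] = centroid
    out["Tc_env_skew"] = skew
    out["Tc_env_kurt"] = kurt
    out["Tc_crest"] = 10.0 * math.log10(env.max() / env.mean())
    out["Tc_mod_depth"] = float((env.max() - env.min()) / (env.max() + env.min()))
    out["Tc_energy_fill"] = float(env.mean() / env.max())
    return out


# ---------------------------------------------------------------------------
# spectral (Sa, Sc)


def _event_spectra(
    signal: AudioSignal, event: AudioEvent, frame_ms: float = 40.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(frames, magnitude spectra, frequency axis) for an event at 50% overlap."""
    fs = signal.sample_rate
    seg = signal.samples[int(round(event.start_s * fs)) : int(round(event.end_s * fs))]
    frame_len = int(round(frame_ms * fs / 1000.0))
    frames = _frames(seg, frame_len, frame_len // 2)
    if frames.shape[1] < frame_len:  # single short frame: zero-pad for the FFT
        frames = np.pad(frames, ((0, 0), (0, frame_len - frames.shape[1])))
    window = np.hanning(frame_len)
    spectra = np.abs(np.fft.rfft(frames * window, axis=1))
    freqs = np.fft.rfftfreq(frame_len, 1.0 / fs)
    return frames, spectra, freqs


def _spectral_scalars(spectra: np.ndarray, freqs: np.ndarray) -> dict[str, np.ndarray]:
    power = spectra**2
    total = power.sum(axis=1)
    total[total <= 0] = 1e-300
    centroid = power @ freqs / total
    bandwidth = np.sqrt((power * (freqs[np.newaxis, :] - centroid[:, np.newaxis]) ** 2).sum(axis=1) / total)
    cum = np.cumsum(power, axis=1) / total[:, np.newaxis]
    rolloff = freqs[np.argmax(cum >= 0.85, axis=1)]
    logp = np.log(np.maximum(power, 1e-300))
    flatness = np.exp(logp.mean(axis=1)) / np.maximum(power.mean(axis=1), 1e-300)
    return {"centroid": centroid, "bandwidth": bandwidth, "rolloff": rolloff, "flatness": flatness}


def _subband_fractions(spectra: np.ndarray, freqs: np.ndarray, n_bands: int = _N_SUBBANDS) -> np.ndarray:
    power = spectra**2
    edges = np.linspace(0.0, freqs[-1], n_bands + 1)
    total = power.sum(axis=1)
    total[total <= 0] = 1e-300
    fractions = np.empty((spectra.shape[0], n_bands))
    for b in range(n_bands):
        mask = (freqs >= edges[b]) & (freqs < edges[b + 1] if b < n_bands - 1 else freqs <= edges[b + 1])
        fractions[:, b] = power[:, mask].sum(axis=1) / total
    return fractions


def spectral_parameterization(signal: AudioSignal, event: AudioEvent, frame_ms: float = 40.0) -> dict[str, float]:
    """Sa_* slots: LPC/MFCC/sub-band means, spreads, and spectral-shape moments."""
    frames, spectra, freqs = _event_spectra(signal, event, frame_ms)
    out = {name: math.nan for name in FEATURE_NAMES if name.startswith("Sa_")}
    if frames.shape[0] == 0:
        return out
    single = frames.shape[0] < 2

    window = np.hanning(frames.shape[1])
    lpcs = np.array([levinson_lpc(f * window, _N_LPC) for f in frames])
    fb = _mel_filterbank(26, frames.shape[1], signal.sample_rate)
    mel_energy = np.maximum(spectra**2 @ fb.T, 1e-300)
    mfcc = dct(np.log(mel_energy), type=2, axis=1, norm="ortho")[:, 1 : _N_MFCC + 1]
    subbands = _subband_fractions(spectra, freqs)

    for i in range(_N_LPC):
        out[f"Sa_lpc_mean_{i+1}"] = float(np.nanmean(lpcs[:, i]))
    for i in range(_N_MFCC):
        out[f"Sa_mfcc_mean_{i+1}"] = float(np.mean(mfcc[:, i]))
        out[f"Sa_mfcc_std_{i+1}"] = math.nan if single else float(np.std(mfcc[:, i]))
    for i in range(_N_SUBBANDS):
        out[f"Sa_subband_mean_{i+1}"] = float(np.mean(subbands[:, i]))
        out[f"Sa_subband_std_{i+1}"] = math.nan if single else float(np.std(subbands[:, i]))

    scalars = _spectral_scalars(spectra, freqs)
    for key in ("centroid", "bandwidth", "rolloff"):
        mean, var, skew, kurt = _moments(scalars[key])
        out[f"Sa_{key}_mean"] = mean
        out[f"Sa_{key}_var"] = math.nan if single else var
        out[f"Sa_{key}_skew"] = math.nan if single else skew
        out[f"Sa_{key}_kurt"] = math.nan if single else kurt
    out["Sa_flatness_mean"] = float(np.mean(scalars["flatness"]))
    out["Sa_flatness_std"] = math.nan if single else float(np.std(scalars["flatness"]))
    return out


# ---------------------------------------------------------------------------
# bio-characteristic frequencies (Sb)


def _frame_pitch(frame: np.ndarray, fs: int, f_lo: float = 30.0, f_hi: float = 400.0, threshold: float = 0.5) -> tuple[float, float]:
    """(pitch Hz or NaN, autocorrelation peak height) for one frame."""
    frame = frame - frame.mean()
    if np.all(frame == 0):
        return math.nan, 0.0
    r = np.correlate(frame, frame, mode="full")[frame.size - 1 :]
    if r[0] <= 0:
        return math.nan, 0.0
    r = r / r[0]
    lag_lo = int(fs / f_hi)
    lag_hi = min(int(fs / f_lo), frame.size - 1)
    if lag_hi <= lag_lo:
        return math.nan, 0.0
    seg = r[lag_lo : lag_hi + 1]
    peaks, props = find_peaks(seg, height=threshold)
    if peaks.size == 0:
        return math.nan, float(seg.max())
    best = peaks[int(np.argmax(props["peak_heights"]))]
    lag = lag_lo + int(best)
    return fs / lag, float(r[lag])


def bio_frequencies(
    signal: AudioSignal,
    event: AudioEvent,
    pitch_frame_ms: float = 80.0,
    pitch_range_hz: tuple[float, float] = (30.0, 400.0),
    voicing_threshold: float = 0.5,
) -> dict[str, float]:
    """Sb_* slots: formants (LPC root method), pitch and pitch-related measures."""
    fs = signal.sample_rate
    seg = signal.samples[int(round(event.start_s * fs)) : int(round(event.end_s * fs))]
    out = {name: math.nan for name in FEATURE_NAMES if name.startswith("Sb_")}
    out["Sb_voiced_fraction"] = 0.0
    out["Sb_pitch_present"] = 0.0
    if seg.size < 32:
        return out

    # formants from LPC roots of 40 ms frames (pre-emphasized), median over frames
    frame_len = int(round(0.040 * fs))
    pre = np.append(seg[0], seg[1:] - 0.97 * seg[:-1])
    frames = _frames(pre, frame_len, frame_len // 2)
    window = np.hanning(frames.shape[1])
    formant_tracks: list[list[tuple[float, float]]] = []
    for f in frames:
        a = levinson_lpc(f * window, _N_LPC)
        if not np.all(np.isfinite(a)):
            continue
        roots = np.roots(np.concatenate(([1.0], a)))
        roots = roots[np.imag(roots) > 0.01]
        freqs_r = np.angle(roots) * fs / (2.0 * math.pi)
        bws = -fs / math.pi * np.log(np.maximum(np.abs(roots), 1e-12))
        cand = sorted(
            (fr, bw) for fr, bw in zip(freqs_r, bws) if 90.0 < fr < fs / 2 - 100.0 and bw < 500.0
        )
        if cand:
            formant_tracks.append(cand[:3])
    for k in range(3):
        vals = [t[k][0] for t in formant_tracks if len(t) > k]
        if vals:
            out[f"Sb_formant{k+1}"] = float(np.median(vals))
            if k == 0:
                out["Sb_formant1_bw"] = float(np.median([t[0][1] for t in formant_tracks if t]))

    # pitch on longer frames so low fundamentals fit several periods
    pframe = int(round(pitch_frame_ms * fs / 1000.0))
    pframes = _frames(seg, pframe, pframe // 2)
    pitches, heights = [], []
    for f in pframes:
        if f.size < pframe:
            continue
        p, h = _frame_pitch(f, fs, *pitch_range_hz, voicing_threshold)
        if np.isfinite(p):
            pitches.append(p)
            heights.append(h)
    n_pframes = max(1, sum(1 for f in pframes if f.size >= pframe))
    if pitches:
        pitches_arr = np.array(pitches)
        out["Sb_pitch"] = float(np.median(pitches_arr))
        out["Sb_voiced_fraction"] = len(pitches) / n_pframes
        out["Sb_pitch_present"] = 1.0
        out["Sb_harmonicity"] = float(np.mean(heights))
        if len(pitches) >= 2:
            out["Sb_pitch_stability"] = float(np.std(pitches_arr) / np.mean(pitches_arr))
            rel = np.abs(np.diff(pitches_arr)) / pitches_arr[:-1]
            out["Sb_jitter"] = float(np.mean(rel))
    return out


def dynamic_frequency_features(signal: AudioSignal, event: AudioEvent, frame_ms: float = 40.0) -> dict[str, float]:
    """Sc_* slots: spectral change over time (flux, correlation, velocities)."""
    _, spectra, freqs = _event_spectra(signal, event, frame_ms)
    out = {name: math.nan for name in FEATURE_NAMES if name.startswith("Sc_")}
    if spectra.shape[0] < 3:
        return out
    norms = np.linalg.norm(spectra, axis=1)
    norms[norms <= 0] = 1e-300
    unit = spectra / norms[:, np.newaxis]
    flux = np.linalg.norm(np.diff(unit, axis=0), axis=1)
    corr = np.sum(unit[1:] * unit[:-1], axis=1)

    mean, var, skew, kurt = _moments(flux)
    out["Sc_flux_mean"], out["Sc_flux_std"] = mean, math.sqrt(var) if var >= 0 else math.nan
    out["Sc_flux_max"], out["Sc_flux_skew"], out["Sc_flux_kurt"] = float(flux.max()), skew, kurt
    out["Sc_flux_median"] = float(np.median(flux))
    out["Sc_corr_mean"] = float(np.mean(corr))
    out["Sc_corr_std"] = float(np.std(corr))
    out["Sc_corr_min"] = float(np.min(corr))
    out["Sc_corr_median"] = float(np.median(corr))

    scalars = _spectral_scalars(spectra, freqs)
    for key, prefix in (("centroid", "Sc_centroid_vel"), ("bandwidth", "Sc_bandwidth_vel"), ("rolloff", "Sc_rolloff_vel")):
        vel = np.diff(scalars[key])
        out[f"{prefix}_meanabs"] = float(np.mean(np.abs(vel)))
        if prefix in ("Sc_centroid_vel", "Sc_bandwidth_vel"):
            out[f"{prefix}_std"] = float(np.std(vel))
        if prefix == "Sc_centroid_vel":
            out[f"{prefix}_max"] = float(np.max(np.abs(vel)))
    subbands = _subband_fractions(spectra, freqs)
    for i in range(_N_SUBBANDS):
        out[f"Sc_subband_var_{i+1}"] = float(np.var(subbands[:, i]))
    return out


# ---------------------------------------------------------------------------
# orchestrator


def extract_all(
    event: AudioEvent,
    signal: AudioSignal,
    track: EnergyTrack,
    periodicity_context_s: float = 12.0,
    lag_range_s: tuple[float, float] = (1.0, 10.0),
    ep_window_s: float = 10.0,
    frame_ms: float = 40.0,
) -> FeatureVector:
    """All 127 slots for one segmented event (deterministic)."""
    values: dict[str, float] = {}
    values.update(periodicity_features(track, event, periodicity_context_s, lag_range_s))
    values["Ta_ep"] = relative_prior_energy(track, event, ep_window_s)
    values.update(duration_features(signal, event))
    values.update(energy_features(track, event))
    values.update(spectral_parameterization(signal, event, frame_ms))
    values.update(bio_frequencies(signal, event))
    values.update(dynamic_frequency_features(signal, event, frame_ms))
    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    return FeatureVector(ordered)
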