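"""Energetic event detection and segmentation on the enhanced signal.

The night is split into one-minute sections.  For each section an adaptive
energy threshold is derived from the histogram of frame energies (in dB):
the histogram mode sits at the background-noise level, and the threshold is
placed at the first energy above the mode whose bin count drops to one
tenth of the mode count.  Thresholds are smoothed across sections with an
order-5 running median.  Runs of frames above threshold become candidate
events; their edges are refined outward by a 10-frame slope fit, close
fragments with similar spectra are merged, and only events lasting
0.2-3.5 s are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from snoredetect.audio_io import AudioSignal, EnergyTrack, FrameSpec, db_from_linear, frame_energy
from snoredetect.enhancement import event_snr

#: event duration bounds (inclusive), seconds
MIN_EVENT_S = 0.2
MAX_EVENT_S = 3.5


@dataclass
class AudioEvent:
    """One detected acoustic event on an energy track."""

    start_frame: int
    end_frame: int  # inclusive
    start_s: float = 0.0
    end_s: float = 0.0
    intensity_db: float = float("nan")
    peak_db: float = float("nan")
    snr_db: float = float("nan")
    label: str | None = None
    score: float | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AdaptiveThreshold:
    """Per-section histogram thresholds before and after median smoothing."""

    e_max: np.ndarray  # histogram mode per section, dB
    e_th_raw: np.ndarray  # raw threshold per section, dB
    e_th: np.ndarray  # median-smoothed threshold per section, dB
    section_bounds: list[tuple[int, int]]  # [start_frame, end_frame) per section


def section_threshold(
    section_db: np.ndarray,
    bin_width_db: float = 1.0,
    fallback_offset_db: float = 6.0,
) -> tuple[float, float]:
    """Histogram-based (e_max, e_th) for one section of dB frame energies.

    e_max is the bin center of the histogram mode; e_th is the smallest bin
    center above e_max whose count has dropped to at most one tenth of the
    mode count.  If no such bin exists (degenerate histograms), e_th falls
    back to ``e_max + fallback_offset_db``.
    """
    section_db = np.asarray(section_db, dtype=float)
    if section_db.size < 10:
        raise ValueError("section must contain at least 10 frames")
    lo = np.floor(section_db.min() / bin_width_db) * bin_width_db
    hi = np.ceil(section_db.max() / bin_width_db) * bin_width_db + bin_width_db
    edges = np.arange(lo, hi + bin_width_db / 2, bin_width_db)
    counts, _ = np.histogram(section_db, bins=edges)
    centers = edges[:-1] + bin_width_db / 2.0
    mode_idx = int(np.argmax(counts))
    e_max = float(centers[mode_idx])
    tenth = counts[mode_idx] / 10.0
    for j in range(mode_idx + 1, counts.size):
        if counts[j] <= tenth:
            return e_max, float(centers[j])
    return e_max, e_max + fallback_offset_db


def smooth_thresholds(e_th: np.ndarray, order: int = 5) -> np.ndarray:
    """Running median of the per-section thresholds; window shrinks at edges."""
    e_th = np.asarray(e_th, dtype=float)
    half = order // 2
    out = np.empty_like(e_th)
    for i in range(e_th.size):
        lo = max(0, i - half)
        hi = min(e_th.size, i + half + 1)
        out[i] = np.median(e_th[lo:hi])
    return out


def _section_bounds(n_frames: int, frame_rate: float, section_s: float = 60.0, min_tail_s: float = 10.0) -> list[tuple[int, int]]:
    """1-minute sections of frames; a final partial section shorter than
    ``min_tail_s`` is merged into the previous one."""
    per_section = max(10, int(round(section_s * frame_rate)))
    bounds = []
    start = 0
    while start < n_frames:
        bounds.append((start, min(start + per_section, n_frames)))
        start += per_section
    if len(bounds) > 1:
        tail_lo, tail_hi = bounds[-1]
        if (tail_hi - tail_lo) < min_tail_s * frame_rate:
            bounds[-2] = (bounds[-2][0], tail_hi)
            bounds.pop()
    return bounds


def compute_thresholds(
    track: EnergyTrack,
    bin_width_db: float = 1.0,
    fallback_offset_db: float = 6.0,
    median_order: int = 5,
    section_s: float = 60.0,
) -> AdaptiveThreshold:
    """Adaptive per-section thresholds over the whole track."""
    bounds = _section_bounds(track.n_frames, track.frame_rate, section_s)
    db = track.db
    e_max = np.empty(len(bounds))
    e_th = np.empty(len(bounds))
    prev = None
    for i, (lo, hi) in enumerate(bounds):
        section = db[lo:hi]
        if section.size >= 10:
            e_max[i], e_th[i] = section_threshold(section, bin_width_db, fallback_offset_db)
            prev = (e_max[i], e_th[i])
        elif prev is not None:  # carry over from previous section
            e_max[i], e_th[i] = prev
        else:
            e_max[i] = np.median(section) if section.size else 0.0
            e_th[i] = e_max[i] + fallback_offset_db
    smoothed = smooth_thresholds(e_th, median_order)
    return AdaptiveThreshold(e_max=e_max, e_th_raw=e_th, e_th=smoothed, section_bounds=bounds)


def detect_candidates(track: EnergyTrack, thresholds: AdaptiveThreshold) -> list[AudioEvent]:
    """Maximal runs of frames whose dB energy strictly exceeds the section threshold."""
    db = track.db
    above = np.zeros(track.n_frames, dtype=bool)
    for (lo, hi), th in zip(thresholds.section_bounds, thresholds.e_th):
        above[lo:hi] = db[lo:hi] > th
    events: list[AudioEvent] = []
    in_run = False
    start = 0
    for i, flag in enumerate(above):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            events.append(AudioEvent(start_frame=start, end_frame=i - 1))
            in_run = False
    if in_run:
        events.append(AudioEvent(start_frame=start, end_frame=track.n_frames - 1))
    return events


def _slope(y: np.ndarray) -> float:
    x = np.arange(y.size, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def refine_edges(
    track: EnergyTrack,
    event: AudioEvent,
    slope_frames: int = 10,
    max_extend_s: float = 2.0,
    min_frame: int = 0,
    max_frame: int | None = None,
    min_slope_db: float = 0.6,
) -> AudioEvent:
    """Extend event boundaries outward while the energy slope outside keeps its sign.

    On each side a least-squares line is fitted to the ``slope_frames``
    energy frames (dB) just outside the current boundary; the boundary moves
    outward one frame at a time for as long as the fitted slope keeps its
    initial sign (on a genuine event flank: rising toward the event on the
    left, falling away on the right).  The search stops at a slope sign
    change, the track or neighbouring-event limit, or after
    ``max_extend_s`` of travel.

    ``min_slope_db`` (dB per frame) is the deadband of the sign test:
    overlapping energy frames are strongly autocorrelated, so on flat
    background the fitted slope of pure noise keeps a spurious sign for
    several frames; a slope whose magnitude falls inside the deadband is
    treated as flat (sign change) rather than as a continuing flank.
    """
    db = track.db
    n = track.n_frames
    max_frame = n - 1 if max_frame is None else max_frame
    max_steps = int(round(max_extend_s * track.frame_rate))

    def extend(boundary: int, step: int, window) -> int:
        initial = None
        for _ in range(max_steps):
            lo, hi = window(boundary)
            if lo < min_frame or hi > max_frame + 1 or not (min_frame < boundary < max_frame):
                break
            s = _slope(db[lo:hi])
            if abs(s) <= min_slope_db:  # flat: treat as a sign change
                break
            if initial is None:
                initial = np.sign(s)
            elif np.sign(s) != initial:
                break
            boundary += step
        return boundary

    start = extend(event.start_frame, -1, lambda b: (b - slope_frames, b))
    end = extend(event.end_frame, +1, lambda b: (b + 1, b + 1 + slope_frames))
    return replace(event, start_frame=start, end_frame=end)


def _segment_spectrum(samples: np.ndarray) -> np.ndarray:
    """Unit-norm, mean-removed log-magnitude spectrum of a short window.

    The mean removal matters: raw magnitude spectra of any two windows of
    the same broadband background are nearly collinear (both follow the
    background's spectral slope), so a similarity measure on them cannot
    separate "two halves of one snore" from "two unrelated noise blips".
    The mean-removed log spectrum compares spectral fine structure
    (harmonics, resonances) instead.
    """
    if samples.size == 0:
        return np.zeros(1)
    spec = np.log(np.abs(np.fft.rfft(samples * np.hanning(samples.size))) + 1e-12)
    spec = spec - spec.mean()
    norm = np.linalg.norm(spec)
    return spec / norm if norm > 0 else spec


def fragmentation_merge(
    signal: AudioSignal,
    track: EnergyTrack,
    events: list[AudioEvent],
    max_gap_s: float = 0.2,
    window_s: float = 0.1,
    merge_threshold: float = 0.7,
) -> list[AudioEvent]:
    """Merge adjacent events split by short gaps when their facing spectra match.

    For each adjacent pair with a gap shorter than ``max_gap_s``, the cosine
    similarity between the magnitude spectra of the earlier event's last
    ``window_s`` and the later event's first ``window_s`` is computed; pairs
    at or above ``merge_threshold`` are merged (iteratively, left to right).
    """
    if not events:
        return []
    fs = signal.sample_rate
    win = int(round(window_s * fs))
    merged = [replace(events[0])]
    for nxt in events[1:]:
        cur = merged[-1]
        gap_s = track.frame_start_s(nxt.start_frame) - track.frame_end_s(cur.end_frame)
        if gap_s < max_gap_s:
            cur_end = cur.end_frame * track.hop_length + track.frame_length
            nxt_start = nxt.start_frame * track.hop_length
            tail = signal.samples[max(0, cur_end - win) : cur_end]
            head = signal.samples[nxt_start : nxt_start + win]
            m = min(tail.size, head.size)
            similarity = float(np.dot(_segment_spectrum(tail[-m:]), _segment_spectrum(head[:m])))
            if similarity >= merge_threshold:
                merged[-1] = replace(cur, end_frame=nxt.end_frame)
                continue
        merged.append(replace(nxt))
    return merged


def duration_filter(
    track: EnergyTrack,
    events: list[AudioEvent],
    min_s: float = MIN_EVENT_S,
    max_s: float = MAX_EVENT_S,
) -> list[AudioEvent]:
    """Keep events with (reported) duration in [min_s, max_s] (inclusive)."""
    kept = []
    for ev in events:
        duration = ev.end_s - ev.start_s
        if duration <= 0:  # events not yet annotated with times: use frame span
            duration = track.frame_end_s(ev.end_frame) - track.frame_start_s(ev.start_frame)
        if min_s - 1e-9 <= duration <= max_s + 1e-9:
            kept.append(ev)
    return kept


def annotate_events(
    track: EnergyTrack,
    events: list[AudioEvent],
    snr_context_s: float = 5.0,
    release_s: float = 0.06,
) -> list[AudioEvent]:
    """Fill in boundary times, intensity, and SNR for segmented events.

    Boundary conventions compensate the deterministic smear of the
    processing chain.  A frame spans ``frame_length`` samples but advances
    by ``hop``; the first frame of a run fires once the event enters the
    tail of its window, so the onset estimate is the frame start plus
    (frame - hop).  At the offset the suppression stage leaks background
    for about one enhancement frame past the event's end (its gains stay
    open while their windows still contain the decaying tail), so
    ``release_s`` is subtracted from the end of the last frame's hop cell.
    """
    spans = [(ev.start_frame, ev.end_frame) for ev in events]
    window_lead_s = (track.frame_length - track.hop_length) / track.sample_rate
    out = []
    for i, ev in enumerate(events):
        others = spans[:i] + spans[i + 1 :]
        seg = track.energies[ev.start_frame : ev.end_frame + 1]
        start_s = track.frame_start_s(ev.start_frame) + window_lead_s
        end_s = (ev.end_frame + 1) * track.hop_length / track.sample_rate - release_s
        end_s = max(end_s, start_s + track.hop_length / track.sample_rate)
        out.append(
            replace(
                ev,
                start_s=start_s,
                end_s=end_s,
                intensity_db=float(db_from_linear(np.mean(seg), track.calibration_offset_db)),
                peak_db=float(db_from_linear(np.max(seg), track.calibration_offset_db)),
                snr_db=event_snr(track, ev.start_frame, ev.end_frame, others, snr_context_s),
            )
        )
    return out


def segment_night(
    signal: AudioSignal,
    frame_spec: FrameSpec | None = None,
    bin_width_db: float = 1.0,
    fallback_offset_db: float = 6.0,
    median_order: int = 5,
    merge_gap_s: float = 0.2,
    merge_window_s: float = 0.1,
    merge_threshold: float = 0.7,
    min_event_s: float = MIN_EVENT_S,
    max_event_s: float = MAX_EVENT_S,
    snr_context_s: float = 5.0,
    min_slope_db: float = 0.6,
    release_s: float = 0.06,
) -> tuple[list[AudioEvent], EnergyTrack]:
    """Full detection/segmentation chain on an (enhanced) signal.

    Returns the detected events (with times, intensity, and SNR filled in)
    and the energy track they were measured on.
    """
    track = frame_energy(signal, frame_spec or FrameSpec())
    thresholds = compute_thresholds(track, bin_width_db, fallback_offset_db, median_order)
    candidates = detect_candidates(track, thresholds)

    refined: list[AudioEvent] = []
    for i, ev in enumerate(candidates):
        lo = refined[-1].end_frame + 1 if refined else 0
        hi = candidates[i + 1].start_frame - 1 if i + 1 < len(candidates) else track.n_frames - 1
        refined.append(refine_edges(track, ev, min_frame=lo, max_frame=hi, min_slope_db=min_slope_db))

    merged = fragmentation_merge(signal, track, refined, merge_gap_s, merge_window_s, merge_threshold)
    annotated = annotate_events(track, merged, snr_context_s, release_s)
    return duration_filter(track, annotated, min_event_s, max_event_s), track
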