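"""End-to-end orchestration: design (training) and validation (scoring) flows.

The validation flow on one night is: enhancement -> event detection and
segmentation -> feature extraction -> AdaBoost scoring -> per-recording
decision threshold -> night report.  The design flow extracts features for
labeled events (detected events matched against a label list, or the label
intervals themselves) and trains the classifier, optionally after forward
feature selection.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from snoredetect.audio_io import AudioSignal, EnergyTrack, FrameSpec, frame_energy
from snoredetect.classification import (
    AdaBoostModel,
    classify_events,
    forward_feature_selection,
    individual_threshold,
    train_adaboost,
)
from snoredetect.config import PipelineConfig
from snoredetect.enhancement import init_noise_template, suppress_noise
from snoredetect.event_detection import AudioEvent, segment_night
from snoredetect.features import FEATURE_NAMES, extract_all
from snoredetect.reporting import NightReport, build_report

logger = logging.getLogger("snoredetect")


def enhance_signal(signal: AudioSignal, config: PipelineConfig) -> AudioSignal:
    template = init_noise_template(
        signal,
        window_s=config.enhancement.init_window_s,
        frame_ms=config.enhancement.frame_ms,
        update_factor=config.enhancement.update_factor,
    )
    return suppress_noise(
        signal,
        template,
        clamp_db=config.enhancement.clamp_db,
        background_percentile=config.enhancement.background_percentile,
        over_subtract=config.enhancement.over_subtract,
        freq_smooth_bins=config.enhancement.freq_smooth_bins,
    )


def detect_events(signal: AudioSignal, config: PipelineConfig) -> tuple[list[AudioEvent], EnergyTrack]:
    det = config.detection
    return segment_night(
        signal,
        frame_spec=FrameSpec(det.frame_ms, det.overlap_fraction),
        bin_width_db=det.bin_width_db,
        fallback_offset_db=det.fallback_offset_db,
        median_order=det.median_order,
        merge_gap_s=det.merge_gap_s,
        merge_window_s=det.merge_window_s,
        merge_threshold=det.merge_threshold,
        min_event_s=det.min_event_s,
        max_event_s=det.max_event_s,
        snr_context_s=det.snr_context_s,
        min_slope_db=det.min_slope_db,
        release_s=det.release_s,
    )


def extract_features(
    events: list[AudioEvent],
    signal: AudioSignal,
    track: EnergyTrack,
    config: PipelineConfig,
) -> np.ndarray:
    feat = config.features
    rows = [
        extract_all(
            ev,
            signal,
            track,
            periodicity_context_s=feat.periodicity_context_s,
            lag_range_s=(feat.lag_min_s, feat.lag_max_s),
            ep_window_s=feat.ep_window_s,
            frame_ms=feat.frame_ms,
        ).to_array()
        for ev in events
    ]
    return np.array(rows) if rows else np.zeros((0, len(FEATURE_NAMES)))


def match_events_to_truth(
    events: list[AudioEvent],
    truth_intervals: list[tuple[float, float, str]],
    min_overlap_s: float = 0.05,
) -> list[str | None]:
    """Label each detected event by the ground-truth interval it overlaps most.

    Events overlapping no interval by at least ``min_overlap_s`` get None.
    """
    labels: list[str | None] = []
    for ev in events:
        best, best_ov = None, min_overlap_s
        for onset, offset, label in truth_intervals:
            ov = min(ev.end_s, offset) - max(ev.start_s, onset)
            if ov >= best_ov:
                best, best_ov = label, ov
        labels.append(best)
    return labels


def events_from_intervals(track: EnergyTrack, intervals: list[tuple[float, float]]) -> list[AudioEvent]:
    """AudioEvents aligned to the track frames for given [onset, offset) times."""
    events = []
    for onset, offset in intervals:
        start = int(round(onset * track.sample_rate / track.hop_length))
        end = int(round((offset * track.sample_rate - track.frame_length) / track.hop_length))
        start = int(np.clip(start, 0, track.n_frames - 1))
        end = int(np.clip(max(end, start), 0, track.n_frames - 1))
        events.append(
            AudioEvent(
                start_frame=start,
                end_frame=end,
                start_s=track.frame_start_s(start),
                end_s=track.frame_end_s(end),
            )
        )
    return events


def run_training(
    corpus: list[tuple[AudioSignal, list[tuple[float, float, str]]]],
    config: PipelineConfig,
    select_features: bool = False,
    enhance: bool = True,
) -> tuple[AdaBoostModel, dict]:
    """Design-phase flow over a labeled corpus of (signal, labeled intervals).

    Events are detected per recording and labeled by overlap with the
    provided intervals; unmatched detections are dropped from training.
    Returns the trained model and a report dict (counts, CV curve when
    feature selection is enabled).
    """
    X_rows, y_rows, group_rows = [], [], []
    for rec_id, (signal, intervals) in enumerate(corpus):
        clean = enhance_signal(signal, config) if enhance else signal
        events, track = detect_events(clean, config)
        labels = match_events_to_truth(events, intervals)
        kept = [(ev, lab) for ev, lab in zip(events, labels) if lab is not None]
        logger.info(
            "recording %d: %d detected events, %d matched to labels", rec_id, len(events), len(kept)
        )
        if not kept:
            continue
        feats = extract_features([ev for ev, _ in kept], clean, track, config)
        X_rows.append(feats)
        y_rows.extend(1.0 if lab == "snore" else -1.0 for _, lab in kept)
        group_rows.extend([rec_id] * len(kept))

    if not X_rows:
        raise ValueError("no labeled events available for training")
    X = np.vstack(X_rows)
    y = np.array(y_rows)
    groups = np.array(group_rows)
    report: dict = {"n_events": int(y.size), "n_snores": int(np.sum(y > 0))}

    feature_names = list(FEATURE_NAMES)
    if select_features:
        selected, curve = forward_feature_selection(
            X,
            y,
            k=config.classifier.k_selection,
            n_folds=config.classifier.n_folds,
            groups=groups,
            max_features=config.classifier.max_features,
        )
        report["selected_features"] = [FEATURE_NAMES[j] for j in selected]
        report["criterion_curve"] = curve
        X = X[:, selected]
        feature_names = [FEATURE_NAMES[j] for j in selected]

    model = train_adaboost(
        X, y, k=config.classifier.k_final, feature_names=feature_names, seed=config.classifier.seed
    )
    return model, report


def run_pipeline(
    signal: AudioSignal,
    model: AdaBoostModel,
    config: PipelineConfig,
    enhance: bool = True,
) -> tuple[NightReport, list[AudioEvent]]:
    """Validation-phase flow on one night; returns the report and scored events."""
    clean = enhance_signal(signal, config) if enhance else signal
    events, track = detect_events(clean, config)
    logger.info("detected %d events", len(events))
    if not events:
        return build_report([], signal.duration_s, 0.0, config.report.epoch_s), []

    X = extract_features(events, clean, track, config)
    if model.feature_names != list(FEATURE_NAMES):  # model trained on a feature subset
        idx = [FEATURE_NAMES.index(n) for n in model.feature_names]
        X = X[:, idx]
    from snoredetect.classification import score as score_fn

    scores = score_fn(model, X)
    cls = config.classifier
    threshold = individual_threshold(
        scores,
        n_bins=cls.threshold_bins,
        smooth_order=cls.threshold_smooth,
        search_region=cls.threshold_region,
        prominence=cls.threshold_prominence,
    )
    labeled = [
        replace(ev, score=float(s), label="snore" if s > threshold.s_th else "nonsnore")
        for ev, s in zip(events, scores)
    ]
    logger.info(
        "classified %d/%d events as snores (S_TH=%.3f, %s)",
        sum(1 for ev in labeled if ev.label == "snore"),
        len(labeled),
        threshold.s_th,
        threshold.method,
    )
    report = build_report(labeled, signal.duration_s, threshold.s_th, config.report.epoch_s)
    return report, labeled
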