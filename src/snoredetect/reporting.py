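"""Evaluation metrics and night-level snore summaries.

Detection performance is summarized by sensitivity (snore detected as
snore), specificity (noise detected as noise) and accuracy, plus ROC/AUC,
Cohen's kappa for scorer agreement, and SNR-stratified accuracy.  Clinical
summaries follow the whole-night reporting conventions: a snore index
(events per hour estimated on 30 s epochs), the objective snore intensity
(OSI, the mean dB intensity of all detected snores), and the fraction of
snores in the <40 / 40-55 / >55 dB intensity bands.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from snoredetect.event_detection import AudioEvent


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label lists must have equal length")
    pos_t, pos_p = y_true > 0, y_pred > 0
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
    )


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as fractions; NaN when a
    denominator is empty."""
    c = confusion_counts(y_true, y_pred)
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    acc = (c.tp + c.tn) / c.total if c.total else math.nan
    return sens, spec, acc


def cohens_kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected agreement between two binary label lists.

    When both raters are constant and identical (expected agreement 1),
    kappa is defined as 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label lists must be non-empty and of equal length")
    pa, pb = a > 0, b > 0
    n = a.size
    p_o = np.mean(pa == pb)
    p_e = np.mean(pa) * np.mean(pb) + np.mean(~pa) * np.mean(~pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points by threshold sweep over unique scores and trapezoidal AUC.

    Equal scores form a single operating point, which makes the AUC equal
    to the normalized Mann-Whitney U statistic (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = y_true > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = pos[order].astype(float)
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(1.0 - pos_sorted)
    # keep only the last index of each tied score block (one operating point)
    last_of_block = np.concatenate((s_sorted[1:] != s_sorted[:-1], [True]))
    tpr = np.concatenate(([0.0], tp[last_of_block] / n_pos))
    fpr = np.concatenate(([0.0], fp[last_of_block] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def accuracy_by_snr(
    snr_db: np.ndarray,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    thresholds_db: np.ndarray,
) -> np.ndarray:
    """Cumulative accuracy over events with SNR at or above each threshold."""
    snr_db = np.asarray(snr_db, dtype=float)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = np.full(len(thresholds_db), math.nan)
    for i, th in enumerate(thresholds_db):
        mask = snr_db >= th
        if mask.any():
            out[i] = float(np.mean((y_true[mask] > 0) == (y_pred[mask] > 0)))
    return out


def snore_index(onsets_s: np.ndarray, total_duration_s: float, epoch_s: float = 30.0) -> np.ndarray:
    """Snore events per hour, estimated per epoch.

    Epochs are anchored at the recording start; the final partial epoch is
    scaled by its actual duration so the index stays in events/hour.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    n_epochs = int(math.ceil(total_duration_s / epoch_s)) if total_duration_s > 0 else 0
    index = np.zeros(n_epochs)
    for e in range(n_epochs):
        lo, hi = e * epoch_s, min((e + 1) * epoch_s, total_duration_s)
        count = int(np.sum((onsets_s >= lo) & (onsets_s < hi)))
        index[e] = count * 3600.0 / (hi - lo) if hi > lo else 0.0
    return index


def osi(snore_intensities_db: np.ndarray) -> float:
    """Objective snore intensity: mean dB intensity of the detected snores."""
    x = np.asarray(snore_intensities_db, dtype=float)
    if x.size == 0:
        return math.nan
    return float(np.mean(x))


def intensity_bands(
    snore_intensities_db: np.ndarray,
    low_db: float = 40.0,
    high_db: float = 55.0,
) -> tuple[float, float, float]:
    """Fractions of snores with intensity <40, 40-55 (inclusive), and >55 dB."""
    x = np.asarray(snore_intensities_db, dtype=float)
    if x.size == 0:
        return (math.nan, math.nan, math.nan)
    low = float(np.mean(x < low_db))
    mid = float(np.mean((x >= low_db) & (x <= high_db)))
    high = float(np.mean(x > high_db))
    return (low, mid, high)


@dataclass
class NightReport:
    """Night-level summary of the classified events."""

    events: pd.DataFrame  # onset_s, offset_s, intensity_db, snr_db, score, label
    total_duration_s: float
    epoch_s: float = 30.0
    snore_index: np.ndarray = field(default_factory=lambda: np.zeros(0))
    osi_db: float = math.nan
    band_fractions: tuple[float, float, float] = (math.nan, math.nan, math.nan)
    s_th: float = 0.0

    @property
    def n_snores(self) -> int:
        return int((self.events["label"] == "snore").sum())

    def to_summary(self) -> dict:
        return {
            "total_duration_s": self.total_duration_s,
            "n_events": int(len(self.events)),
            "n_snores": self.n_snores,
            "osi_db": None if math.isnan(self.osi_db) else round(self.osi_db, 2),
            "band_fractions": {
                "below_40_db": _none_if_nan(self.band_fractions[0]),
                "40_to_55_db": _none_if_nan(self.band_fractions[1]),
                "above_55_db": _none_if_nan(self.band_fractions[2]),
            },
            "epoch_s": self.epoch_s,
            "snore_index_events_per_hr": [round(v, 3) for v in self.snore_index.tolist()],
            "decision_threshold": self.s_th,
        }


def _none_if_nan(v: float) -> float | None:
    return None if (v is None or math.isnan(v)) else round(float(v), 4)


def build_report(
    events: list[AudioEvent],
    total_duration_s: float,
    s_th: float = 0.0,
    epoch_s: float = 30.0,
) -> NightReport:
    """Assemble the night report from classified events."""
    df = pd.DataFrame(
        {
            "onset_s": [round(e.start_s, 3) for e in events],
            "offset_s": [round(e.end_s, 3) for e in events],
            "intensity_db": [e.intensity_db for e in events],
            "snr_db": [e.snr_db for e in events],
            "score": [e.score for e in events],
            "label": [e.label for e in events],
        }
    )
    snores = df[df["label"] == "snore"]
    return NightReport(
        events=df,
        total_duration_s=total_duration_s,
        epoch_s=epoch_s,
        snore_index=snore_index(snores["onset_s"].to_numpy(), total_duration_s, epoch_s),
        osi_db=osi(snores["intensity_db"].to_numpy()),
        band_fractions=intensity_bands(snores["intensity_db"].to_numpy()),
        s_th=s_th,
    )


def render_report(report: NightReport, out_dir: str | Path, plots: bool = True) -> dict[str, Path]:
    """Write events CSV, summary JSON, and (optionally) the standard plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "summary": out / "summary.json",
    }
    report.events.to_csv(paths["events"], index=False)
    paths["summary"].write_text(json.dumps(report.to_summary(), indent=1))
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        snores = report.events[report.events["label"] == "snore"]
        fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
        epochs = np.arange(report.snore_index.size) * report.epoch_s / 3600.0
        axes[0].step(epochs, report.snore_index, where="post")
        axes[0].set_ylabel("snore index (events/hr)")
        axes[1].plot(snores["onset_s"] / 3600.0, snores["intensity_db"], ".", ms=3)
        axes[1].set_ylabel("snore intensity (dB)")
        axes[1].set_xlabel("time (hr)")
        fig.tight_layout()
        paths["timeline"] = out / "snore_timeline.png"
        fig.savefig(paths["timeline"], dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 4))
        if len(snores):
            ax.hist(snores["intensity_db"], bins=np.arange(20, 85, 5), edgecolor="k")
        ax.set_xlabel("snore intensity (dB)")
        ax.set_ylabel("count")
        fig.tight_layout()
        paths["histogram"] = out / "intensity_histogram.png"
        fig.savefig(paths["histogram"], dpi=120)
        plt.close(fig)
    return paths
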