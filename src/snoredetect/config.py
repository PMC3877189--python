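"""Validated pipeline configuration with per-module namespaces.

Defaults are the working parameters of the detection chain: 16 kHz audio,
40 ms enhancement frames with a -25 dB gain clamp, 60 ms / 75%-overlap
energy frames, order-5 threshold median, 200 ms fragmentation gap with
100 ms similarity windows, 0.2-3.5 s event durations, ±12 s periodicity
context with a 1-10 s lag range and a 10 s E_P window, AdaBoost orders
k=100 (feature selection) and k=300 (final model), 10 CV folds, 30 s report
epochs and 40/55 dB intensity bands.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {context!r} must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) in {context!r}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[name] = _build(f.type, value, f"{context}.{name}")
        elif isinstance(value, dict):
            sub = _SECTION_TYPES.get(name)
            kwargs[name] = _build(sub, value, f"{context}.{name}") if sub else value
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class AudioConfig:
    sample_rate: int = 16000
    calibration_offset_db: float = 100.0


@dataclass
class EnhancementConfig:
    frame_ms: float = 40.0
    clamp_db: float = -25.0
    update_factor: float = 0.98
    background_percentile: float = 20.0
    init_window_s: float = 10.0
    over_subtract: float = 4.0
    freq_smooth_bins: int = 9

    def validate(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("enhancement.frame_ms must be positive")
        if self.clamp_db >= 0:
            raise ValueError("enhancement.clamp_db must be negative")


@dataclass
class DetectionConfig:
    frame_ms: float = 60.0
    overlap_fraction: float = 0.75
    bin_width_db: float = 1.0
    fallback_offset_db: float = 6.0
    median_order: int = 5
    merge_gap_s: float = 0.2
    merge_window_s: float = 0.1
    merge_threshold: float = 0.7
    min_event_s: float = 0.2
    max_event_s: float = 3.5
    snr_context_s: float = 5.0
    min_slope_db: float = 0.6
    release_s: float = 0.06

    def validate(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("detection.frame_ms must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("detection.overlap_fraction must lie in [0, 1)")
        if not (0 < self.min_event_s <= self.max_event_s):
            raise ValueError("detection duration bounds must satisfy 0 < min <= max")


@dataclass
class FeatureConfig:
    frame_ms: float = 40.0
    periodicity_context_s: float = 12.0
    lag_min_s: float = 1.0
    lag_max_s: float = 10.0
    ep_window_s: float = 10.0

    def validate(self) -> None:
        if not (0 < self.lag_min_s < self.lag_max_s):
            raise ValueError("feature lag range must satisfy 0 < min < max")


@dataclass
class ClassifierConfig:
    k_final: int = 300
    k_selection: int = 100
    n_folds: int = 10
    max_features: int = 34
    seed: int = 0
    threshold_bins: int = 50
    threshold_smooth: int = 5
    threshold_region: float = 0.25
    threshold_prominence: float = 0.05

    def validate(self) -> None:
        if self.k_final < 1 or self.k_selection < 1:
            raise ValueError("AdaBoost orders must be >= 1")


@dataclass
class ReportConfig:
    epoch_s: float = 30.0
    band_low_db: float = 40.0
    band_high_db: float = 55.0


_SECTION_TYPES = {
    "audio": AudioConfig,
    "enhancement": EnhancementConfig,
    "detection": DetectionConfig,
    "features": FeatureConfig,
    "classifier": ClassifierConfig,
    "report": ReportConfig,
}


@dataclass
class PipelineConfig:
    audio: AudioConfig = field(default_factory=AudioConfig)
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    report: ReportConfig = field(default_factory=ReportConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.enhancement.validate()
        self.detection.validate()
        self.features.validate()
        self.classifier.validate()
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, "pipeline").validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
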