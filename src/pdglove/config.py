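"""Run configuration shared across the assessment pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline-wide parameters.

    Attributes
    ----------
    fs : float
        Sampling frequency in Hz (the accelerometer is sampled at 100 Hz;
        the same default is applied to bend and pressure channels).
    accel_range : float
        Accelerometer acquisition range in g (+/-).
    band : (float, float)
        Tremor pass band in Hz; rest tremor concentrates in 3-8 Hz.
    median_window : int
        Window length of the median pre-filter (odd).
    ewa_alpha : float
        Smoothing weight of the exponentially weighted average filter
        used on slow bend/pressure signals, in (0, 1].
    grade_thresholds : tuple of 4 floats
        Cut points partitioning normalized maximum bend into the five
        flexibility grades F0..F4.
    kmeans_k : int
        Number of strength clusters (six Lovett grades M0..M5).
    split_ratio : float
        Training fraction of the train/test split.
    cv_folds : int
        Folds for cross-validated hyperparameter search.
    """

    fs: float = 100.0
    accel_range: float = 4.0
    band: tuple[float, float] = (3.0, 8.0)
    median_window: int = 5
    ewa_alpha: float = 0.2
    seed: int = 0
    grade_thresholds: tuple[float, float, float, float] = (0.2, 0.4, 0.6, 0.8)
    kmeans_k: int = 6
    split_ratio: float = 0.8
    cv_folds: int = 10
    feature_epsilon: float = 1e-6  # additive guard inside log features, in g

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.fs / 2):
            raise ValueError(f"band {self.band} must satisfy 0 < low < high < fs/2")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be an odd integer >= 1")
        if not (0 < self.ewa_alpha <= 1):
            raise ValueError("ewa_alpha must lie in (0, 1]")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must lie in (0, 1)")
        self.band = (float(low), float(high))
        self.grade_thresholds = tuple(float(t) for t in self.grade_thresholds)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("band", "grade_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        raw = self.to_dict()
        raw["band"] = list(raw["band"])
        raw["grade_thresholds"] = list(raw["grade_thresholds"])
        path.write_text(yaml.safe_dump(raw, sort_keys=False))
        return path
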