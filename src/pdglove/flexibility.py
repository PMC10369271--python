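"""Finger-flexibility grading (F0-F4).

Subjects perform nine gestures; each bend channel is EWA-smoothed,
min-max normalized against the sensor's 0-180 degree range, and the
maximum normalized bend over all gestures, repetitions and fingers is
binned into five grades refining the TAM range-of-motion standard.
F0 is the worst flexibility, F4 the best.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io import BEND_CHANNELS, Recording
from .preprocess import ewa_filter

GESTURES = (
    "Flat hand",
    "Fist",
    "OK",
    "Orchid fingers",
    "A",
    "W",
    "B",
    "U",
    "V",
)

F_GRADES = ("F0", "F1", "F2", "F3", "F4")


@dataclass
class FlexibilityResult:
    per_finger_norm: dict[str, float]
    max_norm: float
    grade: str
    gesture_set: list[str] = field(default_factory=list)


def minmax_normalize(angles, lo: float = 0.0, hi: float = 180.0) -> np.ndarray:
    """Min-max normalization ``(x - lo) / (hi - lo)`` clipped to [0, 1]."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    angles = np.asarray(angles, dtype=float)
    return np.clip((angles - lo) / (hi - lo), 0.0, 1.0)


def grade_flexibility(max_norm: float, thresholds=(0.2, 0.4, 0.6, 0.8)) -> str:
    """Bin a normalized maximum bend into F0..F4.

    Bins are half-open ``[a, b)``: a value exactly on a cut point falls
    in the upper bin.  Monotone non-decreasing in ``max_norm``.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != 4 or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ):
        raise ValueError(f"thresholds must be 4 strictly increasing cut points, got {thresholds}")
    if not (0.0 <= max_norm <= 1.0):
        raise ValueError(f"max_norm must lie in [0, 1], got {max_norm}")
    return F_GRADES[bisect_right(thresholds, max_norm)]


def assess_flexibility(
    recordings: list[Recording], config: RunConfig | None = None
) -> FlexibilityResult:
    """Grade flexibility from one or more gesture bend recordings.

    Each channel is EWA-filtered then normalized; the grade derives from
    the maximum normalized bend reached across every gesture, repetition
    and finger (repetitions are simply extra recordings).
    """
    config = config or RunConfig()
    if not recordings:
        raise ValueError("assess_flexibility needs at least one bend recording")
    per_finger = {name: 0.0 for name in BEND_CHANNELS}
    gesture_set: list[str] = []
    for rec in recordings:
        if rec.kind != "bend":
            raise ValueError(f"expected bend recordings, got kind={rec.kind!r}")
        gesture = rec.meta.get("gesture", "<unknown>")
        if gesture not in GESTURES:
            warnings.warn(f"unknown gesture name {gesture!r}; processing anyway")
        gesture_set.append(gesture)
        for i, name in enumerate(rec.channels):
            smooth = ewa_filter(rec.data[:, i], config.ewa_alpha)
            norm_max = float(minmax_normalize(smooth).max())
            per_finger[name] = max(per_finger.get(name, 0.0), norm_max)
    max_norm = max(per_finger.values())
    return FlexibilityResult(
        per_finger_norm=per_finger,
        max_norm=max_norm,
        grade=grade_flexibility(max_norm, config.grade_thresholds),
        gesture_set=gesture_set,
    )
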