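"""Synthetic signal generators emulating the glove's three signal families.

No public recordings of the glove exist, so every pipeline stage is
exercised on generated data:

* **Tremor** — 5-second triaxial acceleration windows at 100 Hz: a
  sinusoid at a frequency drawn from the 3-8 Hz rest-tremor band, with
  severity-dependent amplitude (class 0 none, class 1 mild, class 2
  severe), per-axis gains modelling a palm-down posture, 1 g gravity on
  the z axis, and additive Gaussian sensor noise.
* **Gesture bend** — per-finger bend-angle profiles for the nine test
  gestures, ramping to a template target scaled by the subject's
  flexion ability.
* **Action pressure** — per-region force pulse trains for the four
  strength-test actions, with peak force proportional to the subject's
  strength level.

Class amplitude ranges are a modelling choice (the severity classes are
separable by amplitude but overlap with noise near the class-1 floor);
they are a stand-in for the unknown clinical amplitude distribution,
never a clinical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .flexibility import GESTURES
from .io import ACCEL_CHANNELS, BEND_CHANNELS, Recording
from .strength import ACTIONS
from .tremor import FEATURE_NAMES, extract_features

AMPLITUDE_RANGES_G = {0: (0.0, 0.0), 1: (0.05, 0.25), 2: (0.4, 1.2)}

# stylized per-finger flexion fractions (thumb..little) for each gesture
GESTURE_TEMPLATES = {
    "Flat hand":      (0.00, 0.00, 0.00, 0.00, 0.00),
    "Fist":           (1.00, 1.00, 1.00, 1.00, 1.00),
    "OK":             (0.90, 0.90, 0.25, 0.20, 0.20),
    "Orchid fingers": (0.60, 0.30, 0.70, 0.50, 0.40),
    "A":              (0.50, 1.00, 1.00, 1.00, 1.00),
    "W":              (0.70, 0.00, 0.00, 0.00, 0.90),
    "B":              (0.90, 0.00, 0.00, 0.00, 0.00),
    "U":              (0.80, 0.00, 0.00, 1.00, 1.00),
    "V":              (0.80, 0.00, 0.00, 1.00, 1.00),
}

PRESSURE_CHANNELS = ("thumb", "index", "middle", "ring", "little", "palm")

# per-region contact gain for each action; "Grasp the cylinder" engages
# every region fully and therefore yields the global force maximum
ACTION_TEMPLATES = {
    "Grasp the cylinder":           (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    "Pinch objects with fingertip": (1.00, 1.00, 0.05, 0.05, 0.05, 0.05),
    "Grasp the ball":               (0.85, 0.85, 0.85, 0.85, 0.85, 0.85),
    "Click objects with finger":    (0.05, 1.00, 0.05, 0.05, 0.05, 0.05),
}

FORCE_PER_LEVEL = 8.0  # peak force units per strength level (level 5 -> 40)


@dataclass
class TremorSimConfig:
    """Generation parameters for one tremor window."""

    severity: int = 0
    fs: float = 100.0
    duration: float = 5.0
    freq: float | None = None          # Hz; drawn uniformly from band if None
    amplitude: float | None = None     # g; drawn from the class range if None
    noise_sd: float = 0.02             # g
    axis_gains: tuple[float, float, float] = (1.0, 0.7, 0.5)
    gravity_g: float = 1.0             # static offset on the z axis
    freq_band: tuple[float, float] = (3.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.severity not in AMPLITUDE_RANGES_G:
            raise ValueError(f"severity must be 0, 1 or 2, got {self.severity}")


def simulate_tremor(cfg: TremorSimConfig) -> tuple[Recording, int]:
    """One labelled triaxial tremor window; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = AMPLITUDE_RANGES_G[cfg.severity]
    amplitude = cfg.amplitude if cfg.amplitude is not None else float(rng.uniform(lo, hi))
    freq = cfg.freq if cfg.freq is not None else float(rng.uniform(*cfg.freq_band))
    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    phases = rng.uniform(0, 2 * np.pi, size=3)
    data = np.empty((n, 3))
    for axis in range(3):
        tone = cfg.axis_gains[axis] * amplitude * np.sin(2 * np.pi * freq * t + phases[axis])
        data[:, axis] = tone + rng.normal(0.0, cfg.noise_sd, size=n)
    data[:, 2] += cfg.gravity_g
    rec = Recording(
        kind="accel",
        channels=list(ACCEL_CHANNELS),
        data=np.clip(data, -4.0, 4.0),
        fs=cfg.fs,
        units="g",
        meta={
            "label": cfg.severity,
            "freq": round(freq, 6),
            "amplitude": round(amplitude, 6),
            "seed": cfg.seed,
        },
    )
    return rec, cfg.severity


def simulate_dataset(
    n: int = 120,
    class_balance: tuple[int, int, int] = (40, 40, 40),
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate ``n`` labelled tremor windows and extract their features.

    Returns a feature table (columns = the nine feature names) and the
    label vector.  Per-sample seeds derive from ``seed`` so the whole
    dataset is reproducible.
    """
    if n < 3:
        raise ValueError("need at least 3 samples (one per class)")
    if sum(class_balance) != n:
        raise ValueError(f"class_balance {class_balance} must sum to n={n}")
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    labels = np.repeat([0, 1, 2], class_balance)
    rows = []
    for label, child in zip(labels, child_seeds):
        rec, _ = simulate_tremor(TremorSimConfig(severity=int(label), seed=int(child)))
        rows.append(extract_features(rec, config).as_array())
    features = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return features, labels


def simulate_gesture_bend(
    gesture: str,
    ability: float = 1.0,
    seed: int = 0,
    fs: float = 100.0,
    duration: float = 5.0,
    noise_sd_deg: float = 2.0,
) -> Recording:
    """Bend-angle recording for one gesture at a given flexion ability.

    ``ability`` in [0, 1] scales the subject's flexion ceiling
    (``ability * 180`` degrees); each finger ramps trapezoidally to its
    template target, holds, and releases.
    """
    if gesture not in GESTURE_TEMPLATES:
        raise ValueError(f"unknown gesture {gesture!r}; expected one of {GESTURES}")
    if not (0.0 <= ability <= 1.0):
        raise ValueError("ability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    # trapezoid: 30% rise, 40% hold, 30% release
    ramp = np.interp(t, [0, 0.3 * duration, 0.7 * duration, duration], [0, 1, 1, 0])
    targets = np.array(GESTURE_TEMPLATES[gesture]) * ability * 180.0
    data = ramp[:, None] * targets[None, :] + rng.normal(0, noise_sd_deg, size=(n, 5))
    return Recording(
        kind="bend",
        channels=list(BEND_CHANNELS),
        data=np.clip(data, 0.0, 180.0),
        fs=fs,
        units="degrees",
        meta={"gesture": gesture, "ability": round(ability, 6), "seed": seed},
    )


def simulate_action_pressure(
    action: str,
    strength_level: int = 5,
    seed: int = 0,
    fs: float = 100.0,
    duration: float = 5.0,
    noise_sd: float = 0.1,
) -> Recording:
    """Pressure recording for one strength-test action.

    Three squeeze pulses over the window; peak force is proportional to
    ``strength_level`` (0..5) with the per-region contact pattern of the
    action.
    """
    if action not in ACTION_TEMPLATES:
        raise ValueError(f"unknown action {action!r}; expected one of {ACTIONS}")
    if not (0 <= strength_level <= 5):
        raise ValueError("strength_level must lie in 0..5")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    pulses = np.zeros(n)
    for center in (0.2 * duration, 0.5 * duration, 0.8 * duration):
        pulses += np.exp(-0.5 * ((t - center) / 0.25) ** 2)
    pulses = np.minimum(pulses, 1.0)
    gains = np.array(ACTION_TEMPLATES[action])
    peak = FORCE_PER_LEVEL * strength_level
    data = peak * pulses[:, None] * gains[None, :]
    data += rng.normal(0, noise_sd, size=data.shape)
    return Recording(
        kind="pressure",
        channels=list(PRESSURE_CHANNELS),
        data=np.clip(data, 0.0, None),
        fs=fs,
        units="force units",
        meta={"action": action, "strength_level": strength_level, "seed": seed},
    )


def simulate_strength_population(
    n_per_level: int = 20, seed: int = 0
) -> np.ndarray:
    """Population of maximum-force values spanning the six strength levels.

    Used to fit the k=6 interval model: each level contributes
    ``n_per_level`` subjects whose measured peak force scatters around
    ``FORCE_PER_LEVEL * level``.
    """
    rng = np.random.default_rng(seed)
    values = []
    for level in range(6):
        center = FORCE_PER_LEVEL * level
        values.append(rng.normal(center, 0.08 * FORCE_PER_LEVEL + 0.3, size=n_per_level))
    return np.clip(np.concatenate(values), 0.0, None)
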