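"""Tremor feature extraction from triaxial acceleration.

The three raw axes are fused into the combined acceleration
a(k) = sqrt(ax^2 + ay^2 + az^2) — with gravity riding on one axis this
is, to first order, the gravity magnitude plus the tremor oscillation —
and the fused signal runs through the chain median -> band-pass
(3-8 Hz) -> adaptive Kalman.  The 9-element feature vector holds six
time-domain statistics of the filtered fused signal (peak-to-peak,
standard deviation, RMS and their logarithms) plus the dominant
in-band frequency of each axis.  The fused-signal dominant frequency is
also computed but excluded from the default vector so the vector
matches the classifier's nine input nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .config import RunConfig
from .io import Recording
from .preprocess import bandpass_filter, kalman_filter, median_filter

FEATURE_NAMES = (
    "p2p", "log_p2p", "sd", "log_sd", "rms", "log_rms",
    "freq_x", "freq_y", "freq_z",
)


def combined_acceleration(ax, ay, az) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes (the fused tremor indicator)."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape) or ax.ndim != 1 or ax.size < 1:
        raise ValueError("axes must be equal-length non-empty 1-D series")
    return np.sqrt(ax**2 + ay**2 + az**2)


def dominant_frequency(x, fs: float, band: tuple[float, float] = (3.0, 8.0)) -> float:
    """Frequency (Hz) of the largest Hann-windowed DFT magnitude within ``band``."""
    x = np.asarray(x, dtype=float)
    if x.size < fs:
        raise ValueError("need at least one second of signal")
    low, high = band
    window = np.hanning(x.size)
    spectrum = np.abs(np.fft.rfft(x * window))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValueError(f"no DFT bins inside band {band} at fs={fs}, n={x.size}")
    return float(freqs[mask][np.argmax(spectrum[mask])])


@dataclass
class FeatureVector:
    """The 9-element tremor descriptor feeding the classifier."""

    p2p: float
    log_p2p: float
    sd: float
    log_sd: float
    rms: float
    log_rms: float
    freq_x: float
    freq_y: float
    freq_z: float
    freq_combined: float = float("nan")  # computed, excluded from the vector

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def extract_features(rec: Recording, config: RunConfig | None = None) -> FeatureVector:
    """Run the fusion + filter chain and compute the tremor feature vector.

    The combined acceleration of the raw axes is median-filtered,
    band-passed to the tremor band and Kalman-filtered; the band-pass
    removes the static gravity component, so what remains is the signed
    tremor oscillation.  Time-domain features are computed on it;
    logarithms use ``ln(x + eps)`` with a small eps so zero-tremor
    windows stay finite.  Dominant frequencies come from the
    median-filtered individual axes via a band-restricted DFT.
    """
    config = config or RunConfig()
    if rec.kind != "accel":
        raise ValueError(f"expected an accel recording, got kind={rec.kind!r}")
    if rec.duration < 1.0:
        raise ValueError("recording shorter than one second")
    axes = [median_filter(rec.channel(name), config.median_window)
            for name in ("ax", "ay", "az")]
    fused_raw = combined_acceleration(*axes)
    fused = kalman_filter(bandpass_filter(fused_raw, rec.fs, *config.band))
    eps = config.feature_epsilon
    p2p = float(np.ptp(fused))
    sd = float(np.std(fused))
    rms = float(np.sqrt(np.mean(fused**2)))
    freqs = [dominant_frequency(x, rec.fs, config.band) for x in axes]
    return FeatureVector(
        p2p=p2p, log_p2p=float(np.log(p2p + eps)),
        sd=sd, log_sd=float(np.log(sd + eps)),
        rms=rms, log_rms=float(np.log(rms + eps)),
        freq_x=freqs[0], freq_y=freqs[1], freq_z=freqs[2],
        freq_combined=dominant_frequency(fused, rec.fs, config.band),
    )
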