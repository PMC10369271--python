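"""Signal conditioning filters.

Four filters cover the glove's needs: an exponentially weighted average
(EWA) smoother for the slow bend/pressure channels, and the tremor chain
median -> band-pass -> adaptive Kalman applied to each accelerometer
axis.  The median filter knocks out isolated spikes, the zero-phase
Butterworth band-pass isolates the 3-8 Hz rest-tremor band from drift
and powerline residue, and the scalar Kalman filter suppresses random
error remaining inside the band.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal


def ewa_filter(x, alpha: float) -> np.ndarray:
    """Exponentially weighted average: ``y[t] = alpha*x[t] + (1-alpha)*y[t-1]``.

    ``y[0] = x[0]``; every output is a convex combination of past inputs,
    so the output never leaves ``[min(x), max(x)]``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("ewa_filter expects a non-empty 1-D series")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    # first-order IIR with initial condition chosen so y[0] == x[0]
    zi = np.array([(1 - alpha) * x[0]])
    y, _ = signal.lfilter([alpha], [1.0, -(1 - alpha)], x, zi=zi)
    return y


def median_filter(x, window: int) -> np.ndarray:
    """Centered sliding median with edge-replication padding."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds signal length {x.size}")
    return ndimage.median_filter(x, size=window, mode="nearest")


def bandpass_filter(x, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The forward-backward pass doubles the effective order and removes
    phase distortion, so tremor peaks are not shifted in time.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < low < high < fs / 2):
        raise ValueError(f"need 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs some margin beyond its padding length
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ValueError(f"signal length {x.size} too short for order-{order} band-pass")
    return signal.sosfiltfilt(sos, x)


@dataclass
class KalmanState:
    """Scalar local-level Kalman state.

    ``x_hat``/``P`` are the running estimate and its variance; ``Q`` and
    ``R`` are the process- and measurement-noise variances, re-estimated
    on the fly from the trailing ``window`` innovations when adaptation
    is enabled.
    """

    x_hat: float
    P: float
    Q: float
    R: float
    window: int = 50

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.R <= 0:
            raise ValueError("initial Q and R must be positive")
        if self.P < 0:
            raise ValueError("initial P must be non-negative")
        if self.window < 1:
            raise ValueError("innovation window must be >= 1")


def default_kalman_state(x, window: int = 50) -> KalmanState:
    """Data-derived initial state for :func:`kalman_filter`.

    ``R`` starts at the variance of the first window of samples (with a
    tiny floor to stay positive) and ``Q`` at 1% of it, so the filter's
    behaviour scales with the signal: multiplying the input by ``c``
    multiplies the output by ``c``.
    """
    x = np.asarray(x, dtype=float)
    head = x[: max(window, 2)]
    r0 = max(float(np.var(head)), 1e-30)
    return KalmanState(x_hat=float(x[0]), P=r0, Q=0.01 * r0, R=r0, window=window)


def kalman_filter(
    x,
    state0: KalmanState | None = None,
    adaptive: bool = True,
) -> np.ndarray:
    """Scalar Kalman filter on a local-level (random-walk) model.

    Predict/update recursion per sample::

        x-  = x_hat          P- = P + Q
        K   = P- / (P- + R)
        x_hat = x- + K * (z - x-)
        P   = (1 - K) * P-

    With ``adaptive=True`` (default) the noise variances are re-estimated
    every step once the trailing ``window`` of samples is full.  The
    measurement-noise variance ``R`` comes from a robust (median absolute
    deviation) estimate on second differences of the raw samples —
    second differencing nearly cancels slow in-band signal while leaving
    sensor noise, whose variance it multiplies by six.  The process
    noise ``Q`` then follows from innovation-covariance consistency:
    the innovation variance estimates ``P + Q + R``, so
    ``Q <- max(mean(d^2) - P - R, tiny)``.  On a clean in-band signal
    ``R`` collapses, the gain approaches one and the signal passes
    through; on a noisy signal ``R`` tracks the noise floor and the
    filter smooths.  With ``adaptive=False`` the recursion is the
    textbook constant-Q/R scalar filter.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("kalman_filter expects a non-empty 1-D series")
    if state0 is None:
        state0 = default_kalman_state(x)
    if x.size < state0.window and adaptive:
        raise ValueError(
            f"signal length {x.size} shorter than innovation window {state0.window}"
        )
    x_hat, P, Q, R = state0.x_hat, state0.P, state0.Q, state0.R
    innovations: deque[float] = deque(maxlen=state0.window)
    samples: deque[float] = deque(maxlen=state0.window)
    out = np.empty_like(x)
    for t, z in enumerate(x):
        samples.append(z)
        x_pred = x_hat
        P_pred = P + Q
        d = z - x_pred
        innovations.append(d)
        if adaptive and len(samples) == state0.window:
            d2 = np.diff(np.asarray(samples), n=2)
            mad = float(np.median(np.abs(d2 - np.median(d2))))
            R = max((mad / 0.6745) ** 2 / 6.0, 1e-30)
            Q = max(float(np.mean(np.square(innovations))) - P - R, 1e-30)
            P_pred = P + Q
        K = P_pred / (P_pred + R)
        x_hat = x_pred + K * d
        P = (1 - K) * P_pred
        out[t] = x_hat
    return out
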