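import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pdglove import (
    KalmanState,
    bandpass_filter,
    ewa_filter,
    kalman_filter,
    median_filter,
)

finite_series = arrays(
    np.float64,
    st.integers(min_value=1, max_value=60),
    elements=st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
)


# -- EWA ---------------------------------------------------------------

def test_ewa_constant_is_fixed_point():
    x = np.full(50, 3.2)
    np.testing.assert_allclose(ewa_filter(x, 0.3), x)


def test_ewa_alpha_one_is_identity():
    x = np.sin(np.arange(30))
    np.testing.assert_allclose(ewa_filter(x, 1.0), x)


def test_ewa_step_response_closed_form():
    # step rising at t=1 (so y[0] = x[0] = 0), alpha = 0.5:
    # the recursion gives y[t] = 1 - 0.5^t for t >= 1, geometrically
    # approaching the new level
    x = np.ones(20)
    x[0] = 0.0
    expected = 1 - 0.5 ** np.arange(20.0)
    expected[0] = 0.0
    np.testing.assert_allclose(ewa_filter(x, 0.5), expected, atol=1e-12)


@pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
def test_ewa_rejects_bad_alpha(alpha):
    with pytest.raises(ValueError):
        ewa_filter(np.ones(5), alpha)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(x=finite_series, alpha=st.floats(0.01, 1.0))
def test_ewa_output_convex_and_length_preserving(x, alpha):
    y = ewa_filter(x, alpha)
    assert y.shape == x.shape
    assert y.min() >= x.min() - 1e-9 * (1 + abs(x.min()))
    assert y.max() <= x.max() + 1e-9 * (1 + abs(x.max()))


# -- median ------------------------------------------------------------

def test_median_monotone_interior_unchanged():
    x = np.arange(20.0)
    y = median_filter(x, 5)
    np.testing.assert_array_equal(y[2:-2], x[2:-2])


def test_median_removes_isolated_spike():
    x = np.full(30, 1.0)
    x[15] = 100.0
    np.testing.assert_array_equal(median_filter(x, 5), np.full(30, 1.0))


def test_median_matches_brute_force_oracle():
    rng = np.random.default_rng(4)
    x = rng.normal(size=101)
    window = 5
    half = window // 2
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    expected = np.array([
        np.sort(padded[i:i + window])[half] for i in range(x.size)
    ])
    np.testing.assert_array_equal(median_filter(x, window), expected)


def test_median_rejects_even_window():
    with pytest.raises(ValueError):
        median_filter(np.ones(10), 4)


# -- bandpass ----------------------------------------------------------

def test_bandpass_passes_in_band_tone():
    fs, f = 100.0, 5.0
    t = np.arange(1000) / fs
    x = np.sin(2 * np.pi * f * t)
    y = bandpass_filter(x, fs, 3, 8)
    # least-squares sinusoid fit on the steady-state section
    seg = slice(200, 800)
    design = np.column_stack([np.sin(2 * np.pi * f * t[seg]),
                              np.cos(2 * np.pi * f * t[seg])])
    coef, *_ = np.linalg.lstsq(design, y[seg], rcond=None)
    amplitude = np.hypot(*coef)
    assert abs(amplitude - 1.0) < 0.05


def test_bandpass_blocks_slow_drift():
    fs = 100.0
    t = np.arange(1000) / fs
    x = np.sin(2 * np.pi * 0.5 * t)
    y = bandpass_filter(x, fs, 3, 8)
    assert np.sqrt(np.mean(y**2)) < 0.05 * np.sqrt(np.mean(x**2))


def test_bandpass_zero_in_zero_out():
    y = bandpass_filter(np.zeros(500), 100.0, 3, 8)
    np.testing.assert_allclose(y, 0.0)


def test_bandpass_rejects_invalid_band():
    with pytest.raises(ValueError):
        bandpass_filter(np.ones(500), 100.0, 8, 3)
    with pytest.raises(ValueError):
        bandpass_filter(np.ones(500), 100.0, 3, 60)


# -- Kalman ------------------------------------------------------------

def textbook_scalar_kalman(z, x0, p0, q, r):
    """Independent constant-Q/R local-level recursion."""
    x_hat, p = x0, p0
    out = []
    for obs in z:
        x_pred = x_hat
        p_pred = p + q
        k = p_pred / (p_pred + r)
        x_hat = x_pred + k * (obs - x_pred)
        p = (1 - k) * p_pred
        out.append(x_hat)
    return np.array(out)


def test_kalman_constant_signal_converges():
    x = np.full(200, 2.5)
    y = kalman_filter(x)
    assert abs(y[100] - 2.5) < 1e-6
    assert abs(y[-1] - 2.5) < 1e-6


def test_kalman_reduces_noise_on_sinusoid():
    fs = 100.0
    t = np.arange(500) / fs
    clean = 0.3 * np.sin(2 * np.pi * 5 * t)
    rng = np.random.default_rng(7)
    noisy = clean + rng.normal(0, 0.2, clean.size)
    filtered = kalman_filter(noisy)
    rmse_noisy = np.sqrt(np.mean((noisy - clean) ** 2))
    rmse_filtered = np.sqrt(np.mean((filtered - clean) ** 2))
    assert rmse_filtered < rmse_noisy


def test_kalman_fixed_qr_matches_textbook_recursion():
    rng = np.random.default_rng(9)
    z = rng.normal(size=300)
    state = KalmanState(x_hat=z[0], P=1.0, Q=0.01, R=0.5, window=50)
    ours = kalman_filter(z, state, adaptive=False)
    oracle = textbook_scalar_kalman(z, z[0], 1.0, 0.01, 0.5)
    np.testing.assert_allclose(ours, oracle, atol=1e-12)


def test_kalman_rejects_nonpositive_noise():
    with pytest.raises(ValueError):
        KalmanState(x_hat=0.0, P=1.0, Q=0.0, R=1.0)
    with pytest.raises(ValueError):
        KalmanState(x_hat=0.0, P=1.0, Q=1.0, R=-1.0)


def test_kalman_length_preserved_and_zero_maps_to_zero():
    y = kalman_filter(np.zeros(120))
    assert y.shape == (120,)
    np.testing.assert_allclose(y, 0.0)
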