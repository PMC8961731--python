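"""Autoregressive (Burg) power spectral density and band-power features.

The signal is modelled as the output of an all-pole linear system driven by
white noise,

    r(n) = -sum_{i=1..k} a_i r(n-i) + u(n),    var(u) = sigma^2,

whose spectrum is

    P_AR(f) = sigma^2 / ( fs * |1 + sum_i a_i exp(-j 2 pi f i / fs)|^2 ).

The 1/fs factor makes the estimate a two-sided density evaluated on
[0, fs/2]: an AR(0) process with sigma^2 = 1 has a flat PSD of 1/fs, and the
process variance equals twice the integral of the density over [0, fs/2]
(see :func:`integrated_power`).  Coefficients are estimated by the Burg
recursion, which minimizes summed forward+backward prediction error through
reflection coefficients and is stable by construction.  Only band means and
ratios are consumed downstream, so the normalization is internal but fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EpochSet, Recording

DEFAULT_ORDER = 16
DEFAULT_GRID_STEP = 0.5


@dataclass
class SpectralEstimate:
    """AR model fit: order, coefficients a_i, innovation variance sigma^2."""

    order: int
    ar_coeffs: np.ndarray
    sigma2: float
    fs: float
    freqs: np.ndarray | None = None
    psd: np.ndarray | None = None


def _burg_batch(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg recursion over a batch of rows.

    Returns (coeffs (B, order), sigma2 (B,)).  Rows are mean-detrended first.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    B, n = x.shape
    if order <= 0:
        raise ValueError("order must be positive")
    if n <= 2 * order:
        raise ValueError(f"need more than {2 * order} samples for order {order}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    x = x - x.mean(axis=1, keepdims=True)
    E = np.mean(x**2, axis=1)
    if np.any(E == 0):
        raise ValueError("constant (zero-variance) signal: AR spectrum undefined")

    ef = x.copy()
    eb = x.copy()
    a = np.zeros((B, order))
    for m in range(order):
        # shift: forward error loses its first sample, backward its last
        efp = ef[:, 1:]
        ebp = eb[:, :-1]
        num = -2.0 * np.sum(efp * ebp, axis=1)
        den = np.sum(efp**2, axis=1) + np.sum(ebp**2, axis=1)
        k_ref = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        # Levinson-Durbin update of the polynomial
        a_prev = a[:, :m].copy()
        a[:, :m] = a_prev + k_ref[:, None] * a_prev[:, ::-1]
        a[:, m] = k_ref
        ef = efp + k_ref[:, None] * ebp
        eb = ebp + k_ref[:, None] * efp
        E = E * (1.0 - k_ref**2)
    return a, E


def burg_fit(signal: np.ndarray, order: int, fs: float = 1.0) -> SpectralEstimate:
    """Fit an AR(order) model to a 1-D signal by the Burg method."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("burg_fit expects a 1-D signal")
    a, sigma2 = _burg_batch(signal, order)
    return SpectralEstimate(order=order, ar_coeffs=a[0], sigma2=float(sigma2[0]), fs=fs)


def _ar_psd_batch(coeffs: np.ndarray, sigma2: np.ndarray, freqs: np.ndarray, fs: float):
    coeffs = np.atleast_2d(coeffs)
    sigma2 = np.atleast_1d(sigma2)
    order = coeffs.shape[1]
    i = np.arange(1, order + 1)
    # denom(f) = |1 + sum_i a_i e^{-j 2 pi f i / fs}|^2
    phase = np.exp(-2j * np.pi * np.outer(freqs, i) / fs)  # (F, order)
    tf = 1.0 + coeffs @ phase.T  # (B, F)
    return sigma2[:, None] / (fs * np.abs(tf) ** 2)


def ar_psd(est: SpectralEstimate, freqs: np.ndarray) -> np.ndarray:
    """Evaluate the AR spectrum of a fitted model on a frequency grid (Hz)."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if freqs.min() < 0 or freqs.max() > est.fs / 2:
        raise ValueError("frequencies must lie in [0, fs/2]")
    psd = _ar_psd_batch(est.ar_coeffs[None, :] if est.order else np.zeros((1, 0)),
                        np.array([est.sigma2]), freqs, est.fs)[0]
    est.freqs = freqs
    est.psd = psd
    return psd


def integrated_power(est: SpectralEstimate, n_grid: int = 2048) -> float:
    """Process variance implied by the AR spectrum (2 * integral over [0, fs/2])."""
    freqs = np.linspace(0, est.fs / 2, n_grid)
    psd = _ar_psd_batch(est.ar_coeffs[None, :], np.array([est.sigma2]), freqs, est.fs)[0]
    return float(2.0 * np.trapezoid(psd, freqs))


def band_grid(band: tuple[float, float], step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    lo, hi = band
    return np.arange(lo, hi + step / 2, step)


def band_power(
    epochs: EpochSet,
    band: tuple[float, float],
    order: int = DEFAULT_ORDER,
    grid_step: float = DEFAULT_GRID_STEP,
) -> np.ndarray:
    """Mean AR-PSD over a band, per epoch and channel.

    The value for each (epoch, channel) is the average of the AR spectrum
    over the band's frequency grid on that window — the "power at this time".
    Returns an (n_epochs, n_channels) matrix.
    """
    lo, hi = band
    if not 0 <= lo < hi <= epochs.fs / 2:
        raise ValueError(f"band {band} outside [0, fs/2] at fs={epochs.fs}")
    N, C, W = epochs.data.shape
    if W <= 2 * order:
        raise ValueError(f"epoch of {W} samples too short for AR order {order}")
    flat = epochs.data.reshape(N * C, W)
    coeffs, sigma2 = _burg_batch(flat, order)
    freqs = band_grid(band, grid_step)
    psd = _ar_psd_batch(coeffs, sigma2, freqs, epochs.fs)
    return psd.mean(axis=1).reshape(N, C)


def batch_band_power(
    series: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = DEFAULT_ORDER,
    grid_step: float = DEFAULT_GRID_STEP,
) -> np.ndarray:
    """Band power of a batch of 1-D series (rows); returns one value per row."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    coeffs, sigma2 = _burg_batch(series, order)
    freqs = band_grid(band, grid_step)
    psd = _ar_psd_batch(coeffs, sigma2, freqs, fs)
    return psd.mean(axis=1)


def spectrogram(
    signal: np.ndarray,
    fs: float,
    window: float = 1.0,
    overlap: float = 0.5,
    order: int = DEFAULT_ORDER,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window AR spectrum of a 1-D signal.

    Returns (times, freqs, power) with power of shape (n_windows, n_freqs);
    times are window centers in seconds.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("spectrogram expects a 1-D signal")
    w = int(round(window * fs))
    step = int(round((window - overlap) * fs))
    if step < 1 or w > signal.size:
        raise ValueError("invalid window/overlap for this signal length")
    if freqs is None:
        freqs = np.arange(0.0, fs / 2 + 1e-9, DEFAULT_GRID_STEP)
    starts = np.arange(0, signal.size - w + 1, step)
    segs = np.stack([signal[s : s + w] for s in starts])
    coeffs, sigma2 = _burg_batch(segs, order)
    power = _ar_psd_batch(coeffs, sigma2, freqs, fs)
    times = (starts + w / 2) / fs
    return times, np.asarray(freqs), power
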