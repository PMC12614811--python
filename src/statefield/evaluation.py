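"""Model performance and receptive-field quality metrics.

VAF (variance accounted for) is the squared Pearson correlation between
observed and predicted responses, expressed as a percentage. VAF_ongoing
isolates the trial-variable part: the observed ongoing activity is each
trial's response minus the trial average, the modelled counterpart is the
full-model minus base-model prediction, and VAF_ongoing is their squared
correlation x 100 over concatenated trials.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .model import RFEstimate, rf_zscore

__all__ = [
    "vaf",
    "vaf_ongoing",
    "compare_rf_quality",
    "filtered_lfp_spectrum",
]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series lengths differ")
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        return np.nan
    return float((a @ b) / den)


def vaf(r_act: np.ndarray, r_est: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted response,
    as a percentage. Multi-trial inputs are concatenated; a trial-invariant
    prediction may be given once and is tiled across trials. Returns NaN
    with a warning when either series is constant.
    """
    r_act = np.asarray(r_act, dtype=float)
    r_est = np.asarray(r_est, dtype=float)
    if r_act.ndim == 2 and r_est.ndim == 1:
        r_est = np.tile(r_est, (r_act.shape[0], 1))
    r = _corr(r_act, r_est)
    if np.isnan(r):
        warnings.warn("constant input; VAF undefined")
        return np.nan
    return 100.0 * r * r


def vaf_ongoing(counts: np.ndarray, r_full: np.ndarray,
                r_base: np.ndarray) -> float:
    """VAF between observed and model-estimated ongoing activity.

    ``counts`` is trials x frames on the test split; ``r_full`` the per-trial
    full-model prediction (trials x frames); ``r_base`` the trial-invariant
    base-model prediction (frames,). Returns NaN with a warning when either
    ongoing series is constant (e.g. zero state filters, or identical
    trials).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    r_full = np.atleast_2d(np.asarray(r_full, dtype=float))
    r_base = np.asarray(r_base, dtype=float)
    if counts.shape != r_full.shape or r_base.shape[0] != counts.shape[1]:
        raise ValueError("shape mismatch between counts and predictions")
    ongoing_obs = counts - counts.mean(axis=0, keepdims=True)
    ongoing_est = r_full - r_base[None, :]
    r = _corr(ongoing_obs, ongoing_est)
    if np.isnan(r):
        warnings.warn("constant ongoing series; VAF_ongoing undefined")
        return np.nan
    return 100.0 * r * r


def compare_rf_quality(rf_base: RFEstimate | np.ndarray,
                       rf_full: RFEstimate | np.ndarray,
                       peak_lag: int | None = None
                       ) -> tuple[float, float, float]:
    """Z quality scores of two restored RFs and their difference.

    Both RFs must share the grid; the peak lag (default: lag of maximal
    spatial variance of the base RF) is applied to both so the comparison is
    like-for-like. Returns (Z_base, Z_full, dZ).
    """
    planes_b = rf_base.rf if isinstance(rf_base, RFEstimate) else np.asarray(rf_base)
    planes_f = rf_full.rf if isinstance(rf_full, RFEstimate) else np.asarray(rf_full)
    if planes_b.shape != planes_f.shape:
        raise ValueError("RF grids differ")
    if peak_lag is None:
        peak_lag = int(np.argmax(planes_b.var(axis=(1, 2))))
    zb = rf_zscore(planes_b, peak_lag=peak_lag).Z
    zf = rf_zscore(planes_f, peak_lag=peak_lag).Z
    if zb is None or zf is None:
        warnings.warn("zero lag-0 SD; Z undefined")
        return np.nan, np.nan, np.nan
    return zb, zf, zf - zb


def filtered_lfp_spectrum(f_lfp: np.ndarray, lfp_samples: np.ndarray,
                          fs: float, n_bins: int = 100) -> np.ndarray:
    """Normalized power spectrum (peak 1) of the LFP after the fitted filter.

    The recorded LFP channel is convolved with the estimated temporal filter
    taps, the PSD estimated by Welch's method, and sampled on a 1 Hz grid
    from 1 to ``n_bins`` Hz for downstream embedding/clustering. An all-zero
    filter returns a flat zero spectrum with a warning.
    """
    taps = np.asarray(f_lfp, dtype=float).ravel()
    x = np.asarray(lfp_samples, dtype=float).ravel()
    if not np.any(taps):
        warnings.warn("all-zero temporal filter; spectrum is identically zero")
        return np.zeros(n_bins)
    y = np.convolve(x, taps, mode="same")
    nperseg = min(int(fs), y.size)
    freqs, psd = sps.welch(y, fs=fs, nperseg=nperseg)
    grid = np.arange(1, n_bins + 1, dtype=float)
    spec = np.interp(grid, freqs, psd)
    peak = spec.max()
    if peak > 0:
        spec = spec / peak
    return spec
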