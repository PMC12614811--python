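"""Trial-to-trial variability and cortical-state statistics.

Four scalar summaries used throughout the package:

* **VR** (variability ratio): one minus the mean leave-one-out squared
  Pearson correlation between each trial and the average of the remaining
  trials. 0 = perfectly repeatable responses, 1 = maximally variable.
* **PLS** (phase-locking strength): resultant length of the unit phasors at
  the LFP-band phases of a neuron's spike times,
  ``PLS = |sum_k exp(i phi(t_k))| / N``.
* **GFI** (global fluctuation index): SD/mean of the channel-averaged binned
  MUA rate during blank intervals; high under synchronized (up/down) states.
* **SI** (synchrony index): fraction of LFP spectral power below 15 Hz,
  ``SI = P_low / (P_low + P_high)`` with P_low over 0.5–15 Hz and P_high over
  15–100 Hz, per spectrogram time bin (30 s windows, 83.33% overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import BandFilteredLFP, LFPChannelSet

__all__ = [
    "TrialResponseMatrix",
    "VRResult",
    "PLSResult",
    "StateIndexSeries",
    "variability_ratio",
    "phase_locking_strength",
    "global_fluctuation_index",
    "synchrony_index",
]


@dataclass
class TrialResponseMatrix:
    """Binned spike counts, trials x frames (one bin per 13.333 ms frame)."""

    counts: np.ndarray
    frame_rate: float = 75.0
    split_label: str = "regularization"

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    def mean_rate_hz(self) -> float:
        """Average firing rate in spikes/s across all trials."""
        return float(self.counts.mean() * self.frame_rate)


@dataclass
class VRResult:
    per_trial_R2: np.ndarray
    mean_R2: float
    vr: float
    degenerate_trials: list[int] = field(default_factory=list)


@dataclass
class PLSResult:
    band: str
    pls: float | None
    n_spikes: int

    @property
    def undefined(self) -> bool:
        return self.pls is None


@dataclass
class StateIndexSeries:
    """Cortical-state index series; SI fields from LFP, GFI fields from MUA."""

    si_times: np.ndarray | None = None
    si: np.ndarray | None = None
    p_low: np.ndarray | None = None
    p_high: np.ndarray | None = None
    gfi_per_interval: np.ndarray | None = None
    fr_ch_avg: np.ndarray | None = None


def _pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def variability_ratio(resp: TrialResponseMatrix | np.ndarray) -> VRResult:
    """Leave-one-out trial reliability and the variability ratio VR.

    For each trial i, R_i^2 is the squared Pearson correlation between that
    trial and the mean of the other n-1 trials; VR = 1 - mean(R_i^2). Trials
    where either series is constant (zero variance) contribute R_i^2 = 0 and
    are flagged — a silent trial is maximally unreliable.
    """
    counts = resp.counts if isinstance(resp, TrialResponseMatrix) else \
        np.atleast_2d(np.asarray(resp, dtype=float))
    n = counts.shape[0]
    if n < 2:
        raise ValueError("VR requires at least 2 trials")
    total = counts.sum(axis=0)
    r2 = np.empty(n)
    degenerate = []
    for i in range(n):
        loo_mean = (total - counts[i]) / (n - 1)
        r = _pearson_r(counts[i], loo_mean)
        if np.isnan(r):
            degenerate.append(i)
            r2[i] = 0.0
        else:
            r2[i] = r * r
    mean_r2 = float(r2.mean())
    return VRResult(per_trial_R2=r2, mean_R2=mean_r2, vr=1.0 - mean_r2,
                    degenerate_trials=degenerate)


def phase_locking_strength(spike_times: np.ndarray,
                           band_lfp: BandFilteredLFP) -> PLSResult:
    """Resultant length of unit phasors at spike-time band phases.

    The phase at each spike time is read by nearest-sample lookup on the
    band's phase trace. Returns an undefined result (pls=None) for zero
    spikes.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return PLSResult(band=band_lfp.band, pls=None, n_spikes=0)
    idx = np.rint((t - band_lfp.t0) * band_lfp.fs).astype(int)
    if np.any(idx < 0) or np.any(idx >= band_lfp.phase.size):
        raise ValueError("spike times outside the band-filtered LFP support")
    phases = band_lfp.phase[idx]
    pls = float(np.abs(np.exp(1j * phases).mean()))
    return PLSResult(band=band_lfp.band, pls=pls, n_spikes=int(t.size))


def global_fluctuation_index(binned_rates: np.ndarray, ddof: int = 1) -> float:
    """GFI = SD / mean of the channel-averaged binned MUA rate.

    ``binned_rates`` is channels x bins (conventionally 100 ms bins over a
    blank inter-sweep interval). Sample SD (ddof=1) by default. Returns NaN
    with a warning when the mean rate is zero.
    """
    rates = np.atleast_2d(np.asarray(binned_rates, dtype=float))
    ch_avg = rates.mean(axis=0)
    m = ch_avg.mean()
    if m == 0:
        warnings.warn("zero mean rate; GFI undefined")
        return np.nan
    return float(ch_avg.std(ddof=ddof) / m)


def synchrony_index(lfp: LFPChannelSet | np.ndarray, fs: float | None = None,
                    channel: int = 0, window_s: float = 30.0,
                    overlap_pct: float = 83.33,
                    low_band: tuple[float, float] = (0.5, 15.0),
                    high_band: tuple[float, float] = (15.0, 100.0)) -> StateIndexSeries:
    """Spectrogram-based synchrony index of a single (deep-layer) LFP channel.

    The PSD is computed in 30 s windows with 83.33% overlap; per time bin,
    P_low integrates 0.5–15 Hz and P_high 15–100 Hz (trapezoid over PSD
    bins), and SI = P_low / (P_low + P_high).
    """
    if isinstance(lfp, LFPChannelSet):
        x = lfp.samples[channel]
        fs = lfp.fs_down
    else:
        x = np.asarray(lfp, dtype=float).ravel()
        if fs is None:
            raise ValueError("fs required for array input")
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than one spectrogram window")
    noverlap = int(round(nperseg * overlap_pct / 100.0))
    freqs, times, psd = sps.spectrogram(x, fs=fs, window="hann",
                                        nperseg=nperseg, noverlap=noverlap,
                                        scaling="density", mode="psd")
    p_low = _band_power(freqs, psd, *low_band)
    p_high = _band_power(freqs, psd, *high_band)
    si = p_low / (p_low + p_high)
    return StateIndexSeries(si_times=times, si=si, p_low=p_low, p_high=p_high)


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float,
                hi: float) -> np.ndarray:
    """Trapezoid-integrated PSD over [lo, hi] per time bin."""
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError("spectral resolution too coarse for band integration")
    return np.trapezoid(psd[mask], freqs[mask], axis=0)
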