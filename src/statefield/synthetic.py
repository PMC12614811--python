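"""Ground-truth neurons, stimuli and cortical-state-coupled LFP/MUA.

Every generator is a pure function of its seed, so each pipeline stage can be
tested and parameter recovery measured without recorded data. The generative
story mirrors the modelled one:

* the stimulus is a 1/f-amplitude ("pink") image movie at 75 Hz, mean
  subtracted and clipped to 8-bit range, in 375-frame / 5 s trials;
* a latent synchrony trace s(t) in [0, 1] — a smoothed up/down telegraph
  process (dwell times of order 0.1–1 s) mixed with a slow drift — drives
  both the LFP (low-frequency power and a delta-band oscillation scale with
  s) and the MUA (event rates scale with s);
* a ground-truth neuron (Gabor spatiotemporal filter, PReLU, Gaussian map,
  rectified power-law output) receives the stimulus drive plus state drives
  through its true LFP/MUA temporal filters, and spikes are per-trial
  Poisson draws. The stimulus is frozen across trials while the state is
  redrawn, so all trial-to-trial structure flows through the shared state
  plus Poisson noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import signals
from .model import (OutputNonlinearity, StatePathwayParams,
                    StimulusPathwayParams, StimulusMovie, combine,
                    forward_state, forward_stimulus, restore_rf)

__all__ = [
    "SyntheticGroundTruth",
    "gen_stimulus",
    "gen_state",
    "make_ground_truth",
    "gen_neuron_recording",
    "make_neuron_dataset",
    "recovery_report",
]

FS_LFP = 3000.0      # post-decimation LFP rate (Hz)
FRAME_RATE = 75.0
FRAMES_PER_TRIAL = 375


@dataclass
class SyntheticGroundTruth:
    """True parameters and provenance for one simulated neuron."""

    stim: StimulusPathwayParams
    state: StatePathwayParams
    out_nl: OutputNonlinearity
    combine_mode: str
    coupling_gain: float
    target_rate_hz: float
    grid: int
    n_lfp_channels: int
    n_mua_channels: int
    seed: int
    seeds: dict = field(default_factory=dict)
    rate_cap: float = 50.0  # spikes per frame bin

    def restored_rf(self):
        return restore_rf(self.stim, shape=(self.grid, self.grid))


def _pink_field(rng: np.random.Generator, shape: tuple[int, int],
                n: int, slope: float = 1.0) -> np.ndarray:
    """n frames of 2-D noise with a 1/f^slope amplitude spectrum."""
    H, W = shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.rfftfreq(W)[None, :]
    f = np.sqrt(fy ** 2 + fx ** 2)
    f[0, 0] = np.inf  # zero out DC
    amp = 1.0 / f ** slope
    spec = (rng.standard_normal((n, H, fx.size))
            + 1j * rng.standard_normal((n, H, fx.size))) * amp[None]
    frames = np.fft.irfft2(spec, s=(H, W))
    return frames


def gen_stimulus(seed: int, n_frames: int = FRAMES_PER_TRIAL,
                 side: int = 30) -> StimulusMovie:
    """Pink-noise image movie: 1/f spatial amplitude, zero mean, 8-bit range.

    Frames are standardized, scaled to an RMS contrast of 40 grey levels and
    clipped to [-128, 127] — the statistics of mean-subtracted natural
    images at the level the encoding model cares about (a 1/f amplitude
    spectrum), without their higher-order structure.
    """
    rng = np.random.default_rng(seed)
    frames = _pink_field(rng, (side, side), n_frames)
    frames -= frames.mean(axis=(1, 2), keepdims=True)
    frames /= frames.std(axis=(1, 2), keepdims=True) + 1e-12
    frames = np.clip(40.0 * frames, -128, 127)
    return StimulusMovie(frames, frame_rate=FRAME_RATE)


def _smooth(x: np.ndarray, sigma_samples: float) -> np.ndarray:
    from scipy import ndimage
    return ndimage.gaussian_filter1d(x, sigma_samples, mode="nearest")


def gen_state(seed: int, duration: float, n_lfp_channels: int = 6,
              n_mua_channels: int = 2, fs: float = FS_LFP,
              mua_base_rate: float = 40.0):
    """Latent synchrony trace with matched LFP channels and MUA events.

    Returns ``(state_trace, LFPChannelSet, MUAEventSeries)`` where
    ``state_trace`` is sampled at ``fs``. The LFP is pink noise whose
    0.5–15 Hz component and a shared 2.5 Hz oscillation scale with s(t),
    while broadband power is state-independent; channels share these
    components with channel-specific pink noise on top. MUA events are
    inhomogeneous Poisson with rate ``mua_base_rate * (0.15 + 0.85 s(t))``
    per channel.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # two-state telegraph, dwell ~ exponential(0.4 s) clipped to [0.1, 1] s
    tele = np.zeros(n)
    pos, level = 0, rng.integers(0, 2)
    while pos < n:
        dwell = float(np.clip(rng.exponential(0.4), 0.1, 1.0))
        end = min(n, pos + int(dwell * fs))
        tele[pos:end] = level
        level = 1 - level
        pos = end
    tele = _smooth(tele, 0.03 * fs)
    drift = _smooth(rng.standard_normal(n), 2.0 * fs)
    drift = (drift - drift.min()) / (np.ptp(drift) + 1e-12)
    s = np.clip(0.7 * tele + 0.3 * drift, 0.0, 1.0)

    def pink1d(lo, hi, rows=1):
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        amp = np.zeros_like(freqs)
        band = (freqs >= lo) & (freqs <= hi)
        amp[band] = 1.0 / np.maximum(freqs[band], 0.5)
        spec = (rng.standard_normal((rows, freqs.size))
                + 1j * rng.standard_normal((rows, freqs.size))) * amp
        x = np.fft.irfft(spec, n=n)
        sd = x.std(axis=-1, keepdims=True)
        return x / np.maximum(sd, 1e-12)

    shared_low = pink1d(0.5, 15.0)[0] * (0.1 + 0.9 * s)
    shared_high = pink1d(15.0, 100.0)[0] * (1.0 - 0.7 * s)
    osc = np.sin(2 * np.pi * 2.5 * t + rng.uniform(0, 2 * np.pi)) * s
    lfp = np.empty((n_lfp_channels, n))
    for ch in range(n_lfp_channels):
        gain = 0.8 + 0.4 * rng.random()
        # channel-specific term sized for ~0.85-0.9 inter-channel correlation,
        # as for contacts ~100 um apart; without it per-channel temporal
        # filters would be unidentifiable (channels collinear)
        lfp[ch] = gain * (shared_low + 0.6 * shared_high + 0.8 * osc) \
            + 0.45 * pink1d(0.5, 100.0)[0]
    lfp_set = signals.LFPChannelSet(lfp, fs_down=fs,
                                    provenance={"synthetic": True, "seed": seed})
    rate = mua_base_rate * (0.15 + 0.85 * s)
    events = []
    for _ in range(n_mua_channels):
        # thinning on the fs grid; per-sample event prob = rate/fs << 1
        p = rate / fs
        hits = np.flatnonzero(rng.random(n) < p)
        events.append(hits / fs)
    mua = signals.MUAEventSeries(events, threshold_sd=5.0, source_fs=fs * 10)
    return s, lfp_set, mua


def _gabor(K: int, sf: float = 0.18, theta: float = 0.6,
           sigma: float = None, phase: float = 0.3) -> np.ndarray:
    if sigma is None:
        sigma = K / 5.0
    g = np.arange(K) - (K - 1) / 2.0
    gx, gy = np.meshgrid(g, g, indexing="ij")
    u = gx * np.cos(theta) + gy * np.sin(theta)
    env = np.exp(-(gx ** 2 + gy ** 2) / (2 * sigma ** 2))
    return env * np.cos(2 * np.pi * sf * u + phase)


#: biphasic temporal profile over 6 lags; peak at lag 2 (-26.7 ms),
#: reversal by lag 5 (-66.7 ms), near-zero at nominally zero latency.
_TEMPORAL = np.array([0.05, 0.55, 1.0, 0.35, -0.45, -0.25])


def _state_filter_shapes(n_lfp: int, n_mua: int, window: int = 150):
    """Smooth unit-norm temporal filter shapes for the state pathways."""
    tt = np.arange(window) / FS_LFP
    f_lfp = np.empty((n_lfp, window))
    for ch in range(n_lfp):
        if ch == 0:
            # low-pass class: smooth early-latency bump
            shape = np.exp(-0.5 * ((np.arange(window) - 45) / 15.0) ** 2)
        else:
            # band-pass classes at frequencies separated by more than the
            # ~20 Hz spectral resolution a 50 ms window affords
            freq = 5.0 + 20.0 * ch
            shape = np.sin(2 * np.pi * freq * tt) * np.hanning(window)
        f_lfp[ch] = shape / np.linalg.norm(shape)
    f_lfp /= np.sqrt(n_lfp)
    bump = np.exp(-0.5 * ((np.arange(window) - 60) / 18.0) ** 2)
    f_mua = np.stack([bump, -0.6 * bump])
    f_mua /= np.linalg.norm(f_mua)
    return f_lfp, f_mua


def _trial_segments(lfp_set, mua, n_frames):
    onsets = np.arange(n_frames) / FRAME_RATE
    lseg = signals.segment_lfp(lfp_set, onsets, condition=False)
    mseg = signals.segment_mua(mua, onsets, fs_down=lfp_set.fs_down)
    return lseg.values, mseg.values


def make_ground_truth(seed: int, grid: int = 16, kernel: int = 9,
                      n_lags: int = 6, alpha: float = 0.6,
                      coupling_gain: float = 0.5,
                      target_rate_hz: float = 30.0,
                      exponent: float = 1.1, n_lfp_channels: int = 6,
                      n_mua_channels: int = 2,
                      mua_weight: float = 1.0) -> SyntheticGroundTruth:
    """Construct a calibrated in-family ground-truth neuron.

    The stimulus drive is normalized (via the map gain) to unit SD over a
    calibration movie; the state filters are scaled so the state drive's SD
    is ``coupling_gain`` in the same units; the output gain is set so the
    mean firing rate over the calibration run is ``target_rate_hz``.
    """
    rng = np.random.default_rng(seed)
    gab = _gabor(kernel, theta=float(rng.uniform(0, np.pi)))
    c = _TEMPORAL[:n_lags, None, None] * gab[None]
    center = (grid / 2.0 + rng.uniform(-1, 1), grid / 2.0 + rng.uniform(-1, 1))
    # sigma = grid/4: the RF envelope spans the frame, as it does after the
    # cropping pass has zoomed the model grid onto the receptive field
    stim_p = StimulusPathwayParams(c, alpha, center, map_sigma=grid / 4.0,
                                   map_gain=1.0)
    calib_stim = gen_stimulus(seed + 101, n_frames=2 * FRAMES_PER_TRIAL,
                              side=grid)
    r = forward_stimulus(stim_p, calib_stim)
    stim_p.map_gain = 1.0 / (r.std() + 1e-12)
    r = r * stim_p.map_gain

    f_lfp, f_mua = _state_filter_shapes(n_lfp_channels, n_mua_channels)
    f_mua = f_mua * mua_weight  # 0 isolates the LFP pathway
    state_p = StatePathwayParams(f_lfp, f_mua)
    _, lfp_set, mua = gen_state(seed + 202, duration=FRAMES_PER_TRIAL
                                / FRAME_RATE + 0.1,
                                n_lfp_channels=n_lfp_channels,
                                n_mua_channels=n_mua_channels)
    lseg, mseg = _trial_segments(lfp_set, mua, FRAMES_PER_TRIAL)
    m_l, m_m = forward_state(state_p, lseg, mseg)
    m = m_l + m_m
    msd = m.std() + 1e-12
    if coupling_gain > 0:
        scale = coupling_gain / msd
    else:
        scale = 0.0
    state_p = StatePathwayParams(f_lfp * scale, f_mua * scale)

    # output gain: mean rate over calibration = target
    m_cal = (m - m.mean()) * (coupling_gain / msd) if coupling_gain > 0 else 0.0
    x = r[:FRAMES_PER_TRIAL] + m_cal
    target_per_bin = target_rate_hz / FRAME_RATE
    base = np.maximum(x, 0.0) ** exponent
    g = target_per_bin / (base.mean() + 1e-12)
    out_nl = OutputNonlinearity(gain=float(g), exponent=exponent)
    return SyntheticGroundTruth(
        stim=stim_p, state=state_p, out_nl=out_nl, combine_mode="additive",
        coupling_gain=coupling_gain, target_rate_hz=target_rate_hz,
        grid=grid, n_lfp_channels=n_lfp_channels,
        n_mua_channels=n_mua_channels, seed=seed,
        seeds={"gt": seed, "calib_stim": seed + 101, "calib_state": seed + 202})


def gen_neuron_recording(gt: SyntheticGroundTruth, stim: StimulusMovie,
                         n_trials: int, seed: int, noiseless: bool = False):
    """Simulate n_trials responses to one frozen movie with redrawn state.

    Returns ``(counts, rates, lfp_segs, mua_segs)`` with shapes
    (n_trials, T), (n_trials, T), (n_trials, T, 150, C_lfp) and
    (n_trials, T, 150, C_mua). With ``noiseless=True`` the counts equal the
    rates (no Poisson draw).
    """
    T = stim.n_frames
    r_stim = forward_stimulus(gt.stim, stim)
    duration = T / FRAME_RATE + 0.1
    counts = np.empty((n_trials, T))
    rates = np.empty((n_trials, T))
    lfp_segs = np.empty((n_trials, T, 150, gt.n_lfp_channels))
    mua_segs = np.empty((n_trials, T, 150, gt.n_mua_channels))
    rng = np.random.default_rng(seed)
    for i in range(n_trials):
        state_seed = int(rng.integers(0, 2 ** 31 - 1))
        _, lfp_set, mua = gen_state(state_seed, duration,
                                    n_lfp_channels=gt.n_lfp_channels,
                                    n_mua_channels=gt.n_mua_channels)
        lseg, mseg = _trial_segments(lfp_set, mua, T)
        m_l, m_m = forward_state(gt.state, lseg, mseg)
        r_est = combine(r_stim, m_l, m_m, gt.out_nl, mode=gt.combine_mode)
        if np.any(r_est > gt.rate_cap):
            raise ValueError("rate cap exceeded; configuration rejected")
        rates[i] = r_est
        counts[i] = r_est if noiseless else rng.poisson(r_est)
        lfp_segs[i] = lseg
        mua_segs[i] = mseg
    return counts, rates, lfp_segs, mua_segs


def make_neuron_dataset(gt: SyntheticGroundTruth, seed: int,
                        n_train_ensembles: int = 10, n_reps: int = 20,
                        frames_per_trial: int = FRAMES_PER_TRIAL,
                        noiseless: bool = False):
    """Build a training/regularization/test dataset for one neuron.

    Training uses ``n_train_ensembles`` distinct single-trial movies
    (concatenated into one stream); the regularization and test splits are
    one frozen movie each, repeated ``n_reps`` times with the cortical state
    redrawn per repeat.
    """
    from .training import NeuronDataset

    rng = np.random.default_rng(seed)

    def block(n_frames, n_trials, stim_seed, rec_seed):
        stim = gen_stimulus(stim_seed, n_frames=n_frames, side=gt.grid)
        counts, rates, lseg, mseg = gen_neuron_recording(
            gt, stim, n_trials, rec_seed, noiseless=noiseless)
        return stim, counts, rates, lseg, mseg

    tr_stims, tr_counts, tr_l, tr_m = [], [], [], []
    for _ in range(n_train_ensembles):
        stim, counts, _, lseg, mseg = block(
            frames_per_trial, 1, int(rng.integers(2 ** 31 - 1)),
            int(rng.integers(2 ** 31 - 1)))
        tr_stims.append(stim.frames)
        tr_counts.append(counts[0])
        tr_l.append(lseg[0])
        tr_m.append(mseg[0])
    stim_reg, y_reg, _, lfp_reg, mua_reg = block(
        frames_per_trial, n_reps, int(rng.integers(2 ** 31 - 1)),
        int(rng.integers(2 ** 31 - 1)))
    stim_test, y_test, _, lfp_test, mua_test = block(
        frames_per_trial, n_reps, int(rng.integers(2 ** 31 - 1)),
        int(rng.integers(2 ** 31 - 1)))
    return NeuronDataset(
        stim_train=np.concatenate(tr_stims), y_train=np.concatenate(tr_counts),
        stim_reg=stim_reg.frames, y_reg=y_reg,
        stim_test=stim_test.frames, y_test=y_test,
        lfp_train=np.concatenate(tr_l), mua_train=np.concatenate(tr_m),
        lfp_reg=lfp_reg, mua_reg=mua_reg,
        lfp_test=lfp_test, mua_test=mua_test)


def _spectral_correlation(f_true: np.ndarray, f_fit: np.ndarray,
                          fs: float = FS_LFP, fmax: float = 100.0,
                          nfft: int = 1024,
                          weights: np.ndarray | None = None) -> float:
    """Correlation of filter amplitude spectra, averaged over channels.

    Compared within 0..fmax: the LFP input is band-limited below 100 Hz,
    so filter components above that are in the input's null space. When
    ``weights`` (input PSD sampled on the rfft grid of ``nfft``) is given,
    the correlation is weighted by it — an estimate can only be faithful at
    frequencies the input actually carries, so the comparison discounts
    near-null directions (for a pink LFP, power at 35 Hz is ~2% of 5 Hz).
    """
    f_true = np.atleast_2d(f_true)
    f_fit = np.atleast_2d(f_fit)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = freqs <= fmax
    w = np.ones(band.sum()) if weights is None else np.asarray(weights)[band]
    w = w / w.sum()
    cors = []
    for a, b in zip(f_true, f_fit):
        A = np.abs(np.fft.rfft(a, n=nfft))[band]
        B = np.abs(np.fft.rfft(b, n=nfft))[band]
        A = A - (w * A).sum()
        B = B - (w * B).sum()
        den = np.sqrt((w * A * A).sum() * (w * B * B).sum())
        if den > 0:
            cors.append(float((w * A * B).sum() / den))
    return float(np.mean(cors)) if cors else np.nan


def reference_lfp_psd(seed: int, fs: float = FS_LFP, nfft: int = 1024,
                      duration: float = 60.0) -> np.ndarray:
    """Welch PSD of a reference generated LFP channel on the rfft grid."""
    from scipy import signal as sps
    _, lfp, _ = gen_state(seed, duration=duration, n_lfp_channels=1)
    freqs, psd = sps.welch(lfp.samples[0], fs=fs, nperseg=4096)
    grid = np.fft.rfftfreq(nfft, 1.0 / fs)
    return np.interp(grid, freqs, psd)


def recovery_report(gt: SyntheticGroundTruth, fitted: dict,
                    data=None) -> dict:
    """Compare a fitted model ladder against the generating parameters.

    ``fitted`` is a model_ladder output dict. Reports the correlation
    between true and fitted restored RFs, the PReLU alpha error, the
    spectral correlation of the LFP temporal filters, per-variant VAF, and
    (when the dataset is supplied) VR and VAF_ongoing on the test split.
    """
    from .evaluation import vaf_ongoing
    from .metrics import variability_ratio

    report = {"coupling_gain": gt.coupling_gain,
              "target_rate_hz": gt.target_rate_hz}
    rf_true = gt.restored_rf().rf
    models = fitted.get("models", {})
    for name, est in models.items():
        rf_fit = restore_rf(est.params_.stim, shape=(gt.grid, gt.grid)).rf
        a = rf_true.ravel() - rf_true.mean()
        b = rf_fit.ravel() - rf_fit.mean()
        den = np.sqrt((a @ a) * (b @ b))
        report[f"rf_correlation_{name}"] = float(a @ b / den) if den else np.nan
        report[f"alpha_error_{name}"] = float(abs(est.alpha_
                                                  - gt.stim.prelu_alpha))
        if est.f_lfp_ is not None:
            report[f"lfp_filter_spectral_correlation_{name}"] = \
                _spectral_correlation(gt.state.f_lfp, est.f_lfp_)
    report["vaf"] = {k: float(v) for k, v in fitted.get("vaf", {}).items()}
    if data is not None:
        report["vr"] = float(variability_ratio(data.y_reg).vr)
        if "base" in models and "m3" in models:
            r_base = models["base"].predict(data.stim_test)
            r_full = models["m3"].predict(data.stim_test,
                                          lfp_segments=data.lfp_test,
                                          mua_segments=data.mua_test)
            report["vaf_ongoing"] = float(
                vaf_ongoing(data.y_test, r_full, r_base))
    return report
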