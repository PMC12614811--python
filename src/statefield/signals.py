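"""LFP/MUA extraction and conditioning from broadband extracellular recordings.

The local field potential (LFP) is the low-frequency (<100 Hz) component of the
extracellular voltage; multi-unit activity (MUA) is the train of large
(|z| > 5 SD) threshold-crossing events in the >600 Hz band. Both are derived
here with zero-phase FIR filters (Kaiser design) so that event and segment
timing is not skewed by filter group delay. Segmentation cuts onset-anchored
150-sample windows used as inputs to the cortical-state pathways of the
encoding model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BroadbandRecording",
    "LFPChannelSet",
    "MUAEventSeries",
    "SegmentTensor",
    "BandFilteredLFP",
    "BAND_EDGES",
    "extract_lfp",
    "extract_mua",
    "remove_spillover",
    "segment_lfp",
    "segment_mua",
    "bandpass_band",
]

#: Canonical LFP frequency bands (Hz): delta, theta, alpha, beta, gamma.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.5),
    "alpha": (7.5, 12.5),
    "beta": (12.5, 30.0),
    "gamma": (30.0, 100.0),
}

# Transition bandwidth (Hz) used when designing each band-pass filter. The
# band edges are fixed by convention; the transition width is a design choice
# balancing filter length against selectivity at the lowest bands.
_BAND_TRANSITION: dict[str, float] = {
    "delta": 0.5,
    "theta": 0.5,
    "alpha": 0.5,
    "beta": 2.0,
    "gamma": 5.0,
}


@dataclass
class BroadbandRecording:
    """Raw multichannel voltage, channels ordered by depth."""

    samples: np.ndarray  # (channels, time)
    fs: float
    channel_depths: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_depths is not None:
            self.channel_depths = np.asarray(self.channel_depths, dtype=float)
            if len(self.channel_depths) != self.samples.shape[0]:
                raise ValueError("one depth per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class LFPChannelSet:
    """Low-passed, decimated field potentials plus the filters that made them."""

    samples: np.ndarray  # (channels, time)
    fs_down: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs_down <= 0:
            raise ValueError("fs_down must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class MUAEventSeries:
    """Per-channel sorted threshold-crossing event times (seconds)."""

    event_times: list[np.ndarray]
    threshold_sd: float
    source_fs: float

    def __post_init__(self):
        self.event_times = [np.asarray(t, dtype=float) for t in self.event_times]
        for t in self.event_times:
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing per channel")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.event_times)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.event_times])


@dataclass
class SegmentTensor:
    """Frame-onset-anchored signal windows, frames x window x channels."""

    values: np.ndarray  # (frames, window_len, channels)
    fs: float
    t_window_ms: float
    n_dropped: int = 0
    alignment: str = "onset"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("segment tensor must be frames x window x channels")

    @property
    def window_len(self) -> int:
        return self.values.shape[1]


@dataclass
class BandFilteredLFP:
    """One canonical band of the LFP with its analytic-signal phase."""

    band: str
    band_edges: tuple[float, float]
    filtered: np.ndarray  # (time,)
    phase: np.ndarray  # (time,), radians in (-pi, pi]
    fs: float
    t0: float = 0.0


def _kaiser_fir(fs: float, pass_edge: float, stop_edge: float,
                atten_db: float = 60.0) -> np.ndarray:
    """Kaiser-window FIR taps for a lowpass/highpass design (pass vs stop edge)."""
    width = abs(stop_edge - pass_edge)
    numtaps, beta = sps.kaiserord(atten_db, width / (0.5 * fs))
    numtaps |= 1  # odd length: symmetric, integer group delay, HP-capable
    cutoff = 0.5 * (pass_edge + stop_edge)
    pass_zero = pass_edge < stop_edge  # lowpass if passband below stopband
    return sps.firwin(numtaps, cutoff, window=("kaiser", beta),
                      pass_zero=pass_zero, fs=fs)


def _kaiser_bandpass(fs: float, low: float, high: float, width: float,
                     atten_db: float = 60.0) -> np.ndarray:
    numtaps, beta = sps.kaiserord(atten_db, width / (0.5 * fs))
    numtaps |= 1
    lo = max(low - width / 2.0, 1e-3)
    hi = min(high + width / 2.0, 0.5 * fs - 1e-3)
    return sps.firwin(numtaps, [lo, hi], window=("kaiser", beta),
                      pass_zero=False, fs=fs)


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering via one symmetric convolution.

    Convolving with taps ⊛ reversed(taps) applies the squared magnitude
    response with exactly zero phase (the FIR analogue of filtfilt, without
    edge padding). Works on the last axis.
    """
    kernel = np.convolve(taps, taps[::-1])
    x = np.atleast_2d(x)
    out = sps.fftconvolve(x, kernel[None, :], mode="same", axes=-1)
    return out


def _notch_60hz(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-stop, half-power at 59/61 Hz."""
    sos = sps.butter(2, [59.0, 61.0], btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def extract_lfp(rec: BroadbandRecording, decimate: int = 10) -> LFPChannelSet:
    """Low-pass (<100 Hz), notch (60 Hz) and decimate broadband data to LFP.

    The low-pass is a zero-phase Kaiser-window FIR (passband 100 Hz, stopband
    120 Hz, 0.1 dB ripple, 60 dB attenuation); line noise is removed with a
    zero-phase Butterworth band-stop with half-power frequencies 59/61 Hz.
    The filtered signal is then decimated ``decimate``-fold (default 10).
    """
    if rec.fs < 1000:
        raise ValueError("extract_lfp requires fs >= 1 kHz")
    if rec.fs / 2.0 <= 120.0:
        raise ValueError("sampling rate too low for a 120 Hz stopband edge")
    taps = _kaiser_fir(rec.fs, 100.0, 120.0)
    if rec.n_samples < taps.size:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than the "
            f"{taps.size}-tap low-pass filter warm-up"
        )
    low = _zero_phase_fir(rec.samples, taps)
    notched = _notch_60hz(low, rec.fs)
    out = notched[:, ::decimate]
    prov = {
        "lowpass": {"type": "fir-kaiser", "pass_hz": 100.0, "stop_hz": 120.0,
                    "ripple_db": 0.1, "atten_db": 60.0, "numtaps": int(taps.size),
                    "zero_phase": True},
        "notch": {"type": "iir-butter", "order": 2, "half_power_hz": [59.0, 61.0],
                  "zero_phase": True},
        "decimation": decimate,
        "source_fs": rec.fs,
    }
    return LFPChannelSet(out, rec.fs / decimate, provenance=prov)


def extract_mua(rec: BroadbandRecording, threshold_sd: float = 5.0,
                refractory_s: float = 1e-3) -> MUAEventSeries:
    """Detect MUA events: |signal| crossings of ``threshold_sd`` x SD in the
    >600 Hz band.

    The high-pass is a zero-phase Kaiser FIR (passband 600 Hz, stopband
    550 Hz, 60 dB attenuation). Consecutive supra-threshold samples form a
    single excursion, and excursions closer than ``refractory_s`` (default
    1 ms — a multiphasic spike waveform crosses threshold more than once)
    merge into one event timed at the first crossing sample.
    """
    if rec.fs < 10000:
        raise ValueError("extract_mua requires fs >= 10 kHz")
    taps = _kaiser_fir(rec.fs, 600.0, 550.0)
    if rec.n_samples < taps.size:
        raise ValueError("recording shorter than the high-pass filter warm-up")
    hp = _zero_phase_fir(rec.samples, taps)
    refr = int(round(refractory_s * rec.fs))
    events = []
    for ch in range(hp.shape[0]):
        x = hp[ch]
        sd = x.std()
        if sd == 0:
            warnings.warn(f"channel {ch} has zero variance; no MUA events")
            events.append(np.empty(0))
            continue
        above = np.abs(x) > threshold_sd * sd
        # one event per excursion, at the first supra-threshold sample
        starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
        if refr > 0 and starts.size > 1:
            kept = [starts[0]]
            for s in starts[1:]:
                if s - kept[-1] >= refr:
                    kept.append(s)
            starts = np.asarray(kept)
        events.append(starts / rec.fs)
    return MUAEventSeries(events, threshold_sd=threshold_sd, source_fs=rec.fs)


def remove_spillover(mua: MUAEventSeries, neuron_spikes: np.ndarray,
                     coincidence_win: float = 0.5e-3) -> tuple[MUAEventSeries, dict]:
    """Remove spike-waveform spillover from neighbouring MUA channels.

    For each channel, events within ``coincidence_win`` seconds of any of the
    sorted neuron's spikes are counted; if they exceed 10% of the channel's
    events, those coincident events are deleted (the channel is otherwise
    untouched). Returns the cleaned series and a per-channel report.
    """
    neuron_spikes = np.sort(np.asarray(neuron_spikes, dtype=float))
    cleaned = []
    report = {"per_channel": [], "coincidence_win_s": coincidence_win}
    for ch, times in enumerate(mua.event_times):
        if times.size == 0 or neuron_spikes.size == 0:
            cleaned.append(times.copy())
            report["per_channel"].append(
                {"channel": ch, "n_events": int(times.size),
                 "n_coincident": 0, "removed": False})
            continue
        idx = np.searchsorted(neuron_spikes, times)
        lo = np.clip(idx - 1, 0, neuron_spikes.size - 1)
        hi = np.clip(idx, 0, neuron_spikes.size - 1)
        nearest = np.minimum(np.abs(times - neuron_spikes[lo]),
                             np.abs(times - neuron_spikes[hi]))
        coincident = nearest <= coincidence_win
        n_co = int(coincident.sum())
        trigger = n_co > 0.10 * times.size
        cleaned.append(times[~coincident] if trigger else times.copy())
        report["per_channel"].append(
            {"channel": ch, "n_events": int(times.size),
             "n_coincident": n_co, "removed": bool(trigger)})
    out = MUAEventSeries(cleaned, threshold_sd=mua.threshold_sd,
                         source_fs=mua.source_fs)
    return out, report


def _onset_indices(frame_onsets: np.ndarray, fs: float) -> np.ndarray:
    """Round onset times (s) to the nearest sample index on a grid at fs."""
    return np.rint(np.asarray(frame_onsets, dtype=float) * fs).astype(int)


def segment_lfp(lfp: LFPChannelSet, frame_onsets: np.ndarray,
                window_len: int = 150, condition: bool = True) -> SegmentTensor:
    """Cut onset-anchored LFP windows of ``window_len`` samples per frame.

    Per the state-pathway conditioning order, the decimated LFP is low-pass
    filtered (<100 Hz) and 60 Hz-notched again at ``fs_down`` before
    segmentation when ``condition`` is true. Frames whose window would run
    past the end of the recording are dropped and counted in ``n_dropped``.
    """
    x = lfp.samples
    if condition:
        if lfp.fs_down / 2.0 > 120.0:
            x = _zero_phase_fir(x, _kaiser_fir(lfp.fs_down, 100.0, 120.0))
        if lfp.fs_down / 2.0 > 61.0:
            x = _notch_60hz(x, lfp.fs_down)
    starts = _onset_indices(frame_onsets, lfp.fs_down)
    if np.any(starts < 0):
        raise ValueError("negative frame onset")
    n = x.shape[1]
    keep = starts + window_len <= n
    segs = np.stack([x[:, s:s + window_len].T for s in starts[keep]], axis=0) \
        if keep.any() else np.empty((0, window_len, x.shape[0]))
    return SegmentTensor(segs, fs=lfp.fs_down,
                         t_window_ms=1e3 * window_len / lfp.fs_down,
                         n_dropped=int((~keep).sum()))


def segment_mua(mua: MUAEventSeries, frame_onsets: np.ndarray, fs_down: float,
                raw_window: int = 1500, reduce: int = 10,
                duration: float | None = None) -> SegmentTensor:
    """Bin MUA events into onset-anchored windows matched to the LFP segments.

    Events are binarized on a grid at ``reduce * fs_down`` (the raw-side
    rate), cut into ``raw_window``-sample windows starting at each frame
    onset, then reduced ``reduce``:1 by summing consecutive samples — summing
    (not striding) so no event is silently dropped. Output is
    frames x (raw_window // reduce) x channels. If ``duration`` (s) is given,
    frames whose window runs past it are dropped and counted.
    """
    grid_fs = reduce * fs_down
    starts = _onset_indices(frame_onsets, grid_fs)
    if np.any(starts < 0):
        raise ValueError("negative frame onset")
    if duration is not None:
        n_avail = int(np.floor(duration * grid_fs))
        keep = starts + raw_window <= n_avail
    else:
        keep = np.ones(starts.shape, dtype=bool)
    horizon = int(starts[keep].max()) + raw_window if keep.any() else raw_window
    trains = np.zeros((mua.n_channels, horizon), dtype=float)
    for ch, times in enumerate(mua.event_times):
        idx = np.rint(times * grid_fs).astype(int)
        idx = idx[(idx >= 0) & (idx < horizon)]
        trains[ch, idx] = 1.0
    out_len = raw_window // reduce
    rows = []
    for s in starts[keep]:
        win = trains[:, s:s + raw_window]  # (channels, raw_window)
        rows.append(win.reshape(mua.n_channels, out_len, reduce).sum(-1).T)
    segs = np.stack(rows, axis=0) if rows else np.empty((0, out_len, mua.n_channels))
    return SegmentTensor(segs, fs=fs_down, t_window_ms=1e3 * out_len / fs_down,
                         n_dropped=int((~keep).sum()))


def bandpass_band(lfp_samples: np.ndarray, fs: float, band: str,
                  t0: float = 0.0) -> BandFilteredLFP:
    """Zero-phase Kaiser FIR band-pass at a canonical band, plus phase.

    ``lfp_samples`` is a single channel, conventionally a 20x-downsampled raw
    trace (~1.5 kHz). The instantaneous phase is the angle of the analytic
    signal (Hilbert transform) of the band-filtered trace.
    """
    if band not in BAND_EDGES:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BAND_EDGES)}")
    low, high = BAND_EDGES[band]
    taps = _kaiser_bandpass(fs, low, high, _BAND_TRANSITION[band])
    x = np.asarray(lfp_samples, dtype=float).ravel()
    filtered = _zero_phase_fir(x, taps)[0]
    phase = np.angle(sps.hilbert(filtered))
    return BandFilteredLFP(band=band, band_edges=(low, high),
                           filtered=filtered, phase=phase, fs=fs, t0=t0)
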