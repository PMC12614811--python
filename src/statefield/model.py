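"""Forward model: stimulus pathway, cortical-state pathways, combination and
output nonlinearity, and receptive-field restoration.

The stimulus pathway is a compact linear–nonlinear cascade:

    r_stim[t] = sum_{x,y} w[x,y] * G( sum_{j,k,tau} c[tau,j,k] s[x-j, y-k, t-tau] )

where ``c`` is a spatiotemporal filter (L temporal lags of one frame,
13.333 ms each), ``G`` a parametric rectifier (PReLU with slope ``alpha`` for
negative inputs; alpha near 1 = linear/simple-type response, near 0 =
rectifying/complex-type), and ``w`` an isotropic Gaussian spatial map that
localizes where the subunit filter operates. State pathways contribute
per-frame modulatory terms m_LFP and m_MUA via 150-tap temporal filters on
onset-anchored LFP/MUA segments. The combined drive passes through a
rectified power law ``N(x) = g * x**exp`` for x > 0, else 0.

Spatial convolution follows the index convention above: zero padding outside
the grid, output same size as the input, kernel anchored at index (0, 0)
(equivalently, full convolution cropped to the leading H x W block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusMovie",
    "StimulusPathwayParams",
    "StatePathwayParams",
    "OutputNonlinearity",
    "EncodingModelParams",
    "RFEstimate",
    "render_map",
    "spatial_conv",
    "forward_stimulus",
    "forward_state",
    "apply_output_nl",
    "combine",
    "restore_rf",
    "rf_zscore",
]


@dataclass
class StimulusMovie:
    """Luminance frames (t x H x W) with a nominal frame rate."""

    frames: np.ndarray
    frame_rate: float = 75.0
    crop_window: tuple[int, int, int] | None = None  # (x0, y0, side) in source px

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be t x H x W")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_onsets(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class StimulusPathwayParams:
    """Trainable parameters of the stimulus-driven pathway."""

    filter_c: np.ndarray          # (L, K, K) lags x space
    prelu_alpha: float            # in [-1, 1]
    map_center: tuple[float, float]  # (mu_x, mu_y) grid coordinates (row, col)
    map_sigma: float              # isotropic SD, grid units, > 0
    map_gain: float = 1.0

    def __post_init__(self):
        self.filter_c = np.asarray(self.filter_c, dtype=float)
        if self.filter_c.ndim != 3:
            raise ValueError("filter_c must be lags x K x K")
        self.prelu_alpha = float(np.clip(self.prelu_alpha, -1.0, 1.0))
        if self.map_sigma <= 0:
            raise ValueError("map_sigma must be positive")

    @property
    def n_lags(self) -> int:
        return self.filter_c.shape[0]


@dataclass
class StatePathwayParams:
    """Temporal filters applied to LFP/MUA segment tensors (window of 150)."""

    f_lfp: np.ndarray | None = None  # (channels, 150)
    f_mua: np.ndarray | None = None  # (2, 150)
    l2_lambda: float = 0.0

    def __post_init__(self):
        if self.f_lfp is not None:
            self.f_lfp = np.atleast_2d(np.asarray(self.f_lfp, dtype=float))
        if self.f_mua is not None:
            self.f_mua = np.atleast_2d(np.asarray(self.f_mua, dtype=float))


@dataclass
class OutputNonlinearity:
    """Rectified power law N(x) = g * x**exp for x > 0, else 0."""

    gain: float = 1.0
    exponent: float = 1.0
    mode: str = "powerlaw_stage"  # relu_stage | powerlaw_stage

    def __post_init__(self):
        if self.gain <= 0 or self.exponent <= 0:
            raise ValueError("gain and exponent must be positive")


@dataclass
class EncodingModelParams:
    """Full parameter set for one model variant."""

    stim: StimulusPathwayParams
    state: StatePathwayParams | None = None
    out_nl: OutputNonlinearity = field(default_factory=OutputNonlinearity)
    combine_mode: str = "additive"  # additive | multiplicative | divisive
    variant: str = "base"           # base | m1 | m2 | m3
    semi_saturation: float = 1.0    # divisive mode only
    state_gain: float = 1.0         # divisive mode only


@dataclass
class RFEstimate:
    """Restored receptive field (filter convolved with map) and quality."""

    rf: np.ndarray  # (L, H, W)
    peak_lag: int | None = None
    zmap: np.ndarray | None = None
    Z: float | None = None


def render_map(center: tuple[float, float], sigma: float, gain: float,
               shape: tuple[int, int]) -> np.ndarray:
    """Isotropic Gaussian map on a 0-based (row, col) grid."""
    gx, gy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    rho = (gx - center[0]) ** 2 + (gy - center[1]) ** 2
    return gain * np.exp(-rho / (2.0 * sigma ** 2))


def spatial_conv(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded convolution, output cropped to the input's leading block.

    out[x, y] = sum_{j,k} kernel[j, k] * image[x - j, y - k], with image
    treated as zero outside its support. Accepts a single image (H x W) or a
    stack (t x H x W); the kernel is 2-D.
    """
    single = image.ndim == 2
    imgs = image[None] if single else image
    T, H, W = imgs.shape
    K = kernel.shape[0]
    P, Q = H + K - 1, W + kernel.shape[1] - 1
    F = np.fft.rfft2(imgs, s=(P, Q))
    G = np.fft.rfft2(kernel, s=(P, Q))
    out = np.fft.irfft2(F * G, s=(P, Q))[:, :H, :W]
    return out[0] if single else out


def _prelu(u: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(u > 0, u, alpha * u)


def forward_stimulus(p: StimulusPathwayParams,
                     s: StimulusMovie | np.ndarray) -> np.ndarray:
    """Per-frame stimulus-driven drive r_stim.

    Spatiotemporal convolution of the filter with the movie (frames before
    t=0 are zero-padded), PReLU applied to the convolution image, then a
    Gaussian-map-weighted spatial sum. Returns shape (t,).
    """
    frames = s.frames if isinstance(s, StimulusMovie) else np.asarray(s, float)
    if frames.ndim != 3:
        raise ValueError("stimulus must be t x H x W")
    T, H, W = frames.shape
    L = p.n_lags
    u = np.zeros((T, H, W))
    for tau in range(L):
        conv = spatial_conv(frames, p.filter_c[tau])
        if tau == 0:
            u += conv
        else:
            u[tau:] += conv[:T - tau]
    a = _prelu(u, p.prelu_alpha)
    w = render_map(p.map_center, p.map_sigma, p.map_gain, (H, W))
    return np.tensordot(a, w, axes=([1, 2], [0, 1]))


def forward_state(p: StatePathwayParams, lfp_segs: np.ndarray | None,
                  mua_segs: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame state-pathway drives (m_LFP, m_MUA).

    Segment tensors are frames x window x channels; each channel's window is
    dotted with that channel's temporal filter and summed over channels.
    """
    m_lfp = m_mua = None
    if p.f_lfp is not None and lfp_segs is not None:
        if lfp_segs.shape[2] != p.f_lfp.shape[0] or \
                lfp_segs.shape[1] != p.f_lfp.shape[1]:
            raise ValueError("LFP segment tensor does not match f_lfp shape")
        m_lfp = np.einsum("twc,cw->t", lfp_segs, p.f_lfp)
    if p.f_mua is not None and mua_segs is not None:
        if mua_segs.shape[2] != p.f_mua.shape[0] or \
                mua_segs.shape[1] != p.f_mua.shape[1]:
            raise ValueError("MUA segment tensor does not match f_mua shape")
        m_mua = np.einsum("twc,cw->t", mua_segs, p.f_mua)
    n = None
    for m in (m_lfp, m_mua):
        if m is not None:
            n = m.shape[0]
    if n is None:
        raise ValueError("at least one state pathway input is required")
    if m_lfp is None:
        m_lfp = np.zeros(n)
    if m_mua is None:
        m_mua = np.zeros(n)
    return m_lfp, m_mua


def apply_output_nl(x: np.ndarray, nl: OutputNonlinearity) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = nl.gain * x[pos] ** nl.exponent
    return out


def combine(r_stim: np.ndarray, m_lfp: np.ndarray, m_mua: np.ndarray,
            nl: OutputNonlinearity, mode: str = "additive",
            semi_saturation: float = 1.0, state_gain: float = 1.0) -> np.ndarray:
    """Combine stimulus and state drives and apply the output nonlinearity.

    additive:        N(r_stim + m_LFP + m_MUA)
    multiplicative:  N(r_stim * (1 + m_LFP + m_MUA)) — the state signal
                     modulates gain around unity so zero filters reduce to
                     the base model
    divisive:        N(r_stim / (sigma_half + state_gain * (m_LFP + m_MUA)))
                     with sigma_half > 0; a denominator touching zero rejects
                     the configuration
    """
    r_stim = np.asarray(r_stim, dtype=float)
    m = np.asarray(m_lfp, dtype=float) + np.asarray(m_mua, dtype=float)
    if r_stim.shape != m.shape:
        raise ValueError("frame counts of stimulus and state drives differ")
    if mode == "additive":
        x = r_stim + m
    elif mode == "multiplicative":
        x = r_stim * (1.0 + m)
    elif mode == "divisive":
        if semi_saturation <= 0:
            raise ValueError("semi-saturation constant must be positive")
        den = semi_saturation + state_gain * m
        if np.any(den <= 0):
            raise ValueError("divisive denominator crosses zero; "
                             "configuration rejected")
        x = r_stim / den
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    return apply_output_nl(x, nl)


def restore_rf(p: StimulusPathwayParams,
               shape: tuple[int, int] | None = None) -> RFEstimate:
    """Receptive-field restoration: per-lag convolution of the filter with
    the rendered Gaussian map.

    The restoration is the effective spatiotemporal weighting the pathway
    applies to the stimulus; it is typically less noisy than the raw filter.
    """
    if shape is None:
        shape = (30, 30)
    w = render_map(p.map_center, p.map_sigma, p.map_gain, shape)
    rf = np.stack([spatial_conv(w, p.filter_c[tau]) for tau in range(p.n_lags)])
    peak = int(np.argmax(rf.var(axis=(1, 2))))
    return RFEstimate(rf=rf, peak_lag=peak)


def rf_zscore(rf: RFEstimate | np.ndarray, peak_lag: int | None = None) -> RFEstimate:
    """RF quality score: z-map at the peak lag, scaled by the lag-0 SD.

    z[i,j] = (rf_peak[i,j] - mean(rf_peak)) / SD(rf_zero-lag); Z = var(z).
    The lag-0 plane serves as a background-noise reference since true RF
    structure is minimal at nominally zero latency. The peak lag defaults to
    the lag of maximal spatial variance. Population statistics (ddof=0).
    """
    if isinstance(rf, RFEstimate):
        planes = rf.rf
        if peak_lag is None:
            peak_lag = rf.peak_lag
    else:
        planes = np.asarray(rf, dtype=float)
    if peak_lag is None:
        peak_lag = int(np.argmax(planes.var(axis=(1, 2))))
    sigma0 = planes[0].std()
    peak = planes[peak_lag]
    if sigma0 == 0:
        return RFEstimate(rf=planes, peak_lag=peak_lag, zmap=None, Z=None)
    z = (peak - peak.mean()) / sigma0
    return RFEstimate(rf=planes, peak_lag=peak_lag, zmap=z, Z=float(z.var()))
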