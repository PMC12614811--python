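"""Staged fitting protocol: three-pass cropping, the model ladder, and
regularization selection.

The ladder fits four variants with shared data and seeds: ``base`` (stimulus
pathway only), ``m1`` (plus one nearby LFP channel), ``m2`` (plus all
grey-matter LFP channels) and ``m3`` (plus two nearby MUA channels).
Neurons whose base-model VAF is below 1% are flagged as unreliable, and
neurons averaging under 1.0 spikes/s are flagged unresponsive; both flags
are advisory (nothing is deleted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .estimator import EncodingRegressor
from .evaluation import vaf
from .model import StimulusMovie

__all__ = [
    "FitConfig",
    "NeuronDataset",
    "downsample_frames",
    "three_pass_crop",
    "fit_model",
    "model_ladder",
]


@dataclass
class FitConfig:
    """Everything needed to reproduce a fit. The seed is mandatory."""

    seed: int
    variant: str = "base"
    combine_mode: str = "additive"
    loss: str = "mse"
    learning_rate: float = 1e-3
    l2_lambda: float | str = 1e-3  # a value, or 'grid' to select on the
    # regularization split from ``lambda_grid``
    lambda_grid: tuple = (1e-4, 1e-3, 1e-2)
    patience: int = 50
    max_epochs: int = 2000
    two_stage: bool = True
    n_lags: int = 6
    kernel_size: int = 9
    grid_size: int = 30
    min_crop_px: int = 120
    m1_channel: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        cfg = asdict(self)
        cfg["lambda_grid"] = list(cfg["lambda_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        import yaml
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "lambda_grid" in cfg:
            cfg["lambda_grid"] = tuple(cfg["lambda_grid"])
        return cls(**cfg)


@dataclass
class NeuronDataset:
    """Aligned training / regularization / test data for one neuron.

    Stimulus arrays are frames x H x W on the model grid. Training responses
    are single-trial (frames,); regularization and test responses are
    trials x frames with per-trial segment tensors (trials x frames x 150 x
    channels) because the cortical state differs across repeats.
    """

    stim_train: np.ndarray
    y_train: np.ndarray
    stim_reg: np.ndarray
    y_reg: np.ndarray
    stim_test: np.ndarray
    y_test: np.ndarray
    lfp_train: np.ndarray | None = None
    mua_train: np.ndarray | None = None
    lfp_reg: np.ndarray | None = None
    mua_reg: np.ndarray | None = None
    lfp_test: np.ndarray | None = None
    mua_test: np.ndarray | None = None
    frame_rate: float = 75.0

    def mean_rate_hz(self) -> float:
        spikes = self.y_train.sum() + self.y_reg.sum() + self.y_test.sum()
        frames = self.y_train.size + self.y_reg.size + self.y_test.size
        return float(spikes / frames * self.frame_rate)


def downsample_frames(frames: np.ndarray, out_side: int) -> np.ndarray:
    """Bilinear resampling of a frame stack to out_side x out_side."""
    frames = np.asarray(frames, dtype=float)
    T, H, W = frames.shape
    if H == out_side and W == out_side:
        return frames
    return ndimage.zoom(frames, (1.0, out_side / H, out_side / W),
                        order=1, grid_mode=True, mode="nearest")


def _estimator_from_config(cfg: FitConfig, variant: str,
                           l2: float) -> EncodingRegressor:
    return EncodingRegressor(
        variant=variant, combine_mode=cfg.combine_mode, n_lags=cfg.n_lags,
        kernel_size=cfg.kernel_size, l2_lambda=l2,
        learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
        patience=cfg.patience, two_stage=cfg.two_stage, loss=cfg.loss,
        random_state=cfg.seed)


def three_pass_crop(stim: StimulusMovie, y_train: np.ndarray,
                    cfg: FitConfig, n_passes: int = 3
                    ) -> tuple[tuple[int, int, int], list]:
    """Locate the receptive field by iterative crop-and-refit.

    Pass 1 fits the base model on the full frame downsampled to the model
    grid; later passes crop a square window spanning the fitted map center
    +/- 3 sigma (converted to source pixels), re-downsample and refit. The
    window side never goes below ``min_crop_px`` source pixels and is
    clamped to the frame. Returns the final (row0, col0, side) window and
    the per-pass fit log. A non-localized map (sigma at or beyond the grid)
    falls back to the full frame with a warning.
    """
    frames = stim.frames
    T, H, W = frames.shape
    G = cfg.grid_size
    window = (0, 0, min(H, W))
    log = []
    for p in range(n_passes):
        r0, c0, side = window
        cropped = frames[:, r0:r0 + side, c0:c0 + side]
        est = _estimator_from_config(cfg, "base", 0.0)
        est.fit(downsample_frames(cropped, G), y_train)
        scale = side / G
        sigma_src = est.map_sigma_ * scale
        log.append({"pass": p + 1, "window": window,
                    "map_center": est.map_center_, "map_sigma": est.map_sigma_})
        # degenerate only when far beyond the grid: a merely broad map still
        # carries a usable center estimate, and an overestimated sigma just
        # clamps the window to the frame
        if est.map_sigma_ >= 1.5 * G:
            warnings.warn("map sigma not localized; using the full frame")
            return (0, 0, min(H, W)), log
        cr = r0 + est.map_center_[0] * scale
        cc = c0 + est.map_center_[1] * scale
        new_side = int(round(max(6.0 * sigma_src, cfg.min_crop_px)))
        new_side = min(new_side, min(H, W))
        nr0 = int(round(np.clip(cr - new_side / 2.0, 0, H - new_side)))
        nc0 = int(round(np.clip(cc - new_side / 2.0, 0, W - new_side)))
        window = (nr0, nc0, new_side)
    return window, log


def fit_model(data: NeuronDataset, cfg: FitConfig) -> tuple[EncodingRegressor, dict]:
    """Fit one variant with early stopping on the regularization split.

    When ``cfg.l2_lambda == 'grid'`` and the variant has a state pathway,
    each candidate penalty is fitted and the one with the lowest
    regularization-split loss is kept.
    """
    variant = cfg.variant

    def segs(which):
        lfp = getattr(data, f"lfp_{which}")
        mua = getattr(data, f"mua_{which}")
        if variant == "base":
            return None, None
        if variant == "m1":
            if lfp is None:
                raise ValueError("variant m1 requires LFP segments")
            return lfp[..., cfg.m1_channel:cfg.m1_channel + 1], None
        if variant == "m2":
            return lfp, None
        return lfp, mua

    lfp_tr, mua_tr = segs("train")
    lfp_rg, mua_rg = segs("reg")
    val = {"X": data.stim_reg, "y": data.y_reg,
           "lfp_segments": lfp_rg, "mua_segments": mua_rg}
    if cfg.l2_lambda == "grid" and variant != "base":
        candidates = cfg.lambda_grid
    else:
        candidates = [0.0 if variant == "base" else float(cfg.l2_lambda)]
    best = None
    trials = []
    for lam in candidates:
        est = _estimator_from_config(cfg, variant, lam)
        est.fit(data.stim_train, data.y_train, lfp_segments=lfp_tr,
                mua_segments=mua_tr, validation_data=val)
        reg_loss = min(h["monitor_loss"].min() for h in est.history_)
        trials.append({"l2_lambda": lam, "reg_loss": float(reg_loss)})
        if best is None or reg_loss < best[1]:
            best = (est, reg_loss, lam)
    est, reg_loss, lam = best
    report = {"variant": variant, "l2_lambda": lam, "reg_loss": reg_loss,
              "lambda_trials": trials,
              "stages": [{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in h.items()} for h in est.history_]}
    return est, report


def model_ladder(data: NeuronDataset, cfg: FitConfig,
                 variants: tuple = ("base", "m1", "m2", "m3")) -> dict:
    """Fit the model ladder with shared data and seed; evaluate test VAF.

    Returns a dict with fitted estimators, per-variant test VAF, the
    base-model reliability flag (VAF < 1%) and the responsiveness flag
    (mean rate < 1.0 spikes/s).
    """
    from dataclasses import replace

    out = {"models": {}, "vaf": {}, "reports": {}}
    for variant in variants:
        if variant == "m1" and (data.lfp_test is None):
            continue
        if variant == "m3" and (data.mua_test is None):
            continue
        vcfg = replace(cfg, variant=variant)
        est, report = fit_model(data, vcfg)
        out["models"][variant] = est
        out["reports"][variant] = report
        if variant == "base":
            pred = est.predict(data.stim_test)
        else:
            lfp = data.lfp_test
            mua = data.mua_test if variant == "m3" else None
            if variant == "m1":
                lfp = lfp[..., vcfg.m1_channel:vcfg.m1_channel + 1]
            pred = est.predict(data.stim_test, lfp_segments=lfp,
                               mua_segments=mua)
        out["vaf"][variant] = vaf(data.y_test, pred)
    out["mean_rate_hz"] = data.mean_rate_hz()
    out["unresponsive"] = out["mean_rate_hz"] < 1.0
    out["low_base_vaf"] = bool(out["vaf"].get("base", np.nan) < 1.0)
    return out
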