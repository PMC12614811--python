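"""Gradient fitting of the encoding model, packaged as an sklearn-style
estimator.

The model is small (a spatiotemporal filter, a parametric rectifier, a
Gaussian map, per-channel 150-tap state filters and a two-parameter output
nonlinearity), so gradients are computed analytically and optimized with
full-batch Adam. FFT-based convolution with a precomputed stimulus spectrum
makes each epoch cheap enough for desk-scale fitting on one CPU.

Training follows a two-stage protocol: stage 1 fixes the output nonlinearity
to a ReLU and estimates the pathway filters (spatiotemporal filter from a
Glorot-normal draw, PReLU alpha at 0.5, Gaussian map centered with SD equal
to the image side, state filters from zero); stage 2 warm-starts the
spatiotemporal filter from stage 1, re-initializes the remaining parameters
the same way, and re-trains with a trainable rectified power law
N(x) = g * x**exp. L2 regularization applies to the LFP/MUA temporal filters
only. Early stopping monitors the held-out (regularization-set) loss with a
configurable patience and restores the best-epoch weights.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .model import (EncodingModelParams, OutputNonlinearity,
                    StatePathwayParams, StimulusPathwayParams)

__all__ = ["EncodingRegressor"]

_EPS = 1e-12


class _Convolver:
    """FFT-based spatiotemporal convolution against a fixed movie.

    Precomputes the padded 2-D spectra of all frames once; per epoch only a
    complex multiply-accumulate over lags and one inverse FFT are needed,
    for both the forward pass and the filter gradient (a correlation).
    """

    def __init__(self, frames: np.ndarray, kernel_size: int, n_lags: int,
                 single: bool = True):
        self.T, self.H, self.W = frames.shape
        self.K = kernel_size
        self.L = n_lags
        self.P = self.H + kernel_size - 1
        self.Q = self.W + kernel_size - 1
        # single precision by default: the fit is noise-dominated far above
        # float32 eps; pass single=False for finite-difference checks
        dtype = np.complex64 if single else np.complex128
        self.S_fft = np.fft.rfft2(frames, s=(self.P, self.Q)).astype(dtype)
        self.S_conj = self.S_fft.conj()
        self._buf = np.empty_like(self.S_fft)
        self._tmp = np.empty_like(self.S_fft)

    def forward(self, c: np.ndarray) -> np.ndarray:
        """u[t] = sum_tau conv2(s[t - tau], c[tau]), zero-padded history."""
        C_fft = np.fft.rfft2(c, s=(self.P, self.Q)).astype(self.S_fft.dtype)
        acc = self._buf
        acc[:] = 0
        tmp = self._tmp
        for tau in range(self.L):
            if tau == 0:
                np.multiply(self.S_fft, C_fft[0], out=tmp)
                acc += tmp
            else:
                np.multiply(self.S_fft[:self.T - tau], C_fft[tau],
                            out=tmp[tau:])
                acc[tau:] += tmp[tau:]
        u = np.fft.irfft2(acc, s=(self.P, self.Q))[:, :self.H, :self.W]
        return np.ascontiguousarray(u, dtype=np.float64)

    def grad_c(self, q: np.ndarray) -> np.ndarray:
        """d loss / d c given q = d loss / d u, via spatial correlation."""
        Q_fft = np.fft.rfft2(q, s=(self.P, self.Q)).astype(self.S_fft.dtype)
        out = np.empty((self.L, self.K, self.K))
        tmp = self._tmp
        for tau in range(self.L):
            if tau == 0:
                np.multiply(Q_fft, self.S_conj, out=tmp)
                acc = tmp.sum(axis=0)
            else:
                np.multiply(Q_fft[tau:], self.S_conj[:self.T - tau],
                            out=tmp[:self.T - tau])
                acc = tmp[:self.T - tau].sum(axis=0)
            out[tau] = np.fft.irfft2(acc, s=(self.P, self.Q))[:self.K, :self.K]
        return out


class _Adam:
    def __init__(self, keys, lr):
        self.lr = lr
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0
        self.b1, self.b2 = 0.9, 0.999

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def _as_trials(y, segs_lfp, segs_mua):
    """Normalize targets/segments to (R, T) / (R, T, W, C)."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    out = []
    for s in (segs_lfp, segs_mua):
        if s is None:
            out.append(None)
        else:
            s = np.asarray(s, dtype=float)
            if s.ndim == 3:
                s = s[None]
            if s.shape[0] != y.shape[0] or s.shape[1] != y.shape[1]:
                raise ValueError("segment tensor shape does not match targets")
            out.append(s)
    return y, out[0], out[1]


class EncodingRegressor(RegressorMixin, BaseEstimator):
    """Stimulus + cortical-state encoding model of per-frame spike counts.

    Parameters
    ----------
    variant : {'base', 'm1', 'm2', 'm3'}
        Model ladder rung: stimulus pathway only; plus one LFP channel; plus
        all LFP channels; plus two MUA channels. The variant constrains which
        segment inputs `fit` expects (m1 requires a single-channel LFP
        tensor; m3 requires both LFP and MUA tensors).
    combine_mode : {'additive', 'multiplicative', 'divisive'}
        How state drives combine with the stimulus drive before the output
        nonlinearity.
    n_lags : int
        Temporal extent of the spatiotemporal filter in frames (13.333 ms
        each); default 6 spans 0 to -66.7 ms.
    kernel_size : int
        Side of the spatial filter kernel on the downsampled grid.
    l2_lambda : float
        L2 penalty on the LFP/MUA temporal filters (only).
    two_stage : bool
        Run the ReLU stage followed by the trainable power-law stage.
    loss : {'mse', 'poisson'}
        Training objective; evaluation is VAF-based regardless.
    random_state : int or None
        Seeds the Glorot filter initialization; fits are deterministic given
        the seed.

    Attributes (after fit)
    ----------------------
    filter_c_, alpha_, map_center_, map_sigma_, map_gain_ : stimulus pathway
    f_lfp_, f_mua_ : state-pathway temporal filters (None when absent)
    gain_, exponent_ : output nonlinearity (1, 1 after the ReLU stage)
    params_ : EncodingModelParams bundling the above
    history_ : per-stage training curves and best epochs
    """

    def __init__(self, variant="base", combine_mode="additive", n_lags=6,
                 kernel_size=9, l2_lambda=1e-3, learning_rate=1e-3,
                 max_epochs=2000, patience=50, two_stage=True, loss="mse",
                 random_state=None, verbose=0):
        self.variant = variant
        self.combine_mode = combine_mode
        self.n_lags = n_lags
        self.kernel_size = kernel_size
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.two_stage = two_stage
        self.loss = loss
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, *, lfp_segments=None, mua_segments=None,
            validation_data=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be frames x H x W")
        y, lfp, mua = _as_trials(y, lfp_segments, mua_segments)
        if y.shape[1] != X.shape[0]:
            raise ValueError("targets do not match the number of frames")
        self._check_variant_inputs(lfp, mua)
        if self.loss not in ("mse", "poisson"):
            raise ValueError("loss must be 'mse' or 'poisson'")

        T, H, W = X.shape
        conv = _Convolver(X, self.kernel_size, self.n_lags)
        val = None
        if validation_data is not None:
            Xv = np.asarray(validation_data["X"], dtype=float)
            yv, lfpv, muav = _as_trials(validation_data["y"],
                                        validation_data.get("lfp_segments"),
                                        validation_data.get("mua_segments"))
            if yv.size == 0:
                raise ValueError("empty regularization split")
            val = (_Convolver(Xv, self.kernel_size, self.n_lags), yv, lfpv, muav)

        rng = np.random.default_rng(self.random_state)
        params = self._init_params(rng, (H, W), lfp, mua)
        self.history_ = []
        params = self._run_stage(params, conv, y, lfp, mua, val, stage=1)
        if self.two_stage:
            p2 = self._init_params(rng, (H, W), lfp, mua)
            p2["c"] = params["c"].copy()  # warm start the filter only
            p2["g"] = np.float64(1.0)
            p2["exp"] = np.float64(1.0)
            params = self._run_stage(p2, conv, y, lfp, mua, val, stage=2)
        self._store(params, (H, W))
        return self

    def _check_variant_inputs(self, lfp, mua):
        v = self.variant
        if v not in ("base", "m1", "m2", "m3"):
            raise ValueError(f"unknown variant {v!r}")
        if v == "base":
            return
        if lfp is None:
            raise ValueError(f"variant {v!r} requires lfp_segments")
        if v == "m1" and lfp.shape[-1] != 1:
            raise ValueError("variant 'm1' uses exactly one LFP channel")
        if v == "m3" and mua is None:
            raise ValueError("variant 'm3' requires mua_segments")
        if v in ("m1", "m2") and mua is not None:
            raise ValueError(f"variant {v!r} does not take mua_segments")

    def _init_params(self, rng, shape, lfp, mua):
        H, W = shape
        K, L = self.kernel_size, self.n_lags
        fan = K * K * L
        c = rng.normal(0.0, np.sqrt(2.0 / (fan + fan)), size=(L, K, K))
        params = {
            "c": c,
            "alpha": np.float64(0.5),
            "mu": np.array([(H - 1) / 2.0, (W - 1) / 2.0]),
            "log_sigma": np.float64(np.log(H)),
            "log_gain": np.float64(0.0),
            "g": np.float64(1.0),
            "exp": np.float64(1.0),
        }
        if self.variant != "base":
            params["f_lfp"] = np.zeros((lfp.shape[-1], lfp.shape[-2]))
        if self.variant == "m3":
            params["f_mua"] = np.zeros((mua.shape[-1], mua.shape[-2]))
        if self.combine_mode == "divisive":
            params["semi_sat"] = np.float64(1.0)
            params["state_gain"] = np.float64(1.0)
        return params

    # -------------------------------------------------------------- forward
    def _grid(self, H, W):
        cached = getattr(self, "_grid_cache", None)
        if cached is None or cached[0].shape != (H, W):
            gx, gy = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            self._grid_cache = cached = (gx.astype(float), gy.astype(float))
        return cached

    def _forward(self, params, conv, lfp, mua, n_trials, stage):
        H, W = conv.H, conv.W
        u = conv.forward(params["c"])
        alpha = float(params["alpha"])
        a = np.where(u > 0, u, alpha * u)
        gx, gy = self._grid(H, W)
        sigma = np.exp(float(params["log_sigma"]))
        rho = (gx - params["mu"][0]) ** 2 + (gy - params["mu"][1]) ** 2
        # mass-normalized Gaussian: decouples the map's width from its gain,
        # so sigma can localize without dragging the output scale with it
        G = np.exp(-rho / (2 * sigma ** 2))
        S = G.sum()
        wmap = np.exp(float(params["log_gain"])) * G / S
        r_stim = np.tensordot(a, wmap, axes=([1, 2], [0, 1]))  # (T,)
        m = np.zeros((n_trials, conv.T))
        if "f_lfp" in params and lfp is not None:
            m += np.einsum("rtwc,cw->rt", lfp, params["f_lfp"])
        if "f_mua" in params and mua is not None:
            m += np.einsum("rtwc,cw->rt", mua, params["f_mua"])
        mode = self.combine_mode
        if mode == "additive":
            x = r_stim[None, :] + m
        elif mode == "multiplicative":
            x = r_stim[None, :] * (1.0 + m)
        elif mode == "divisive":
            den = np.maximum(float(params["semi_sat"])
                             + float(params["state_gain"]) * m, 1e-6)
            x = r_stim[None, :] / den
        else:
            raise ValueError(f"unknown combine mode {mode!r}")
        g = float(params["g"]) if stage == 2 else 1.0
        e = float(params["exp"]) if stage == 2 else 1.0
        pos = x > 0
        r = np.zeros_like(x)
        xe = np.power(np.where(pos, x, 1.0), e)
        r[pos] = g * xe[pos]
        cache = dict(u=u, a=a, wmap=wmap, r_stim=r_stim, m=m, x=x, pos=pos,
                     xe=xe, g=g, e=e, G=G, S=S, rho=rho, sigma=sigma)
        if mode == "divisive":
            cache["den"] = den
        return r, cache

    def _data_loss(self, r, y):
        if self.loss == "poisson":
            return float(np.mean(r - y * np.log(r + _EPS)))
        return float(np.mean((r - y) ** 2))

    def _penalty(self, params):
        pen = 0.0
        for k in ("f_lfp", "f_mua"):
            if k in params:
                pen += self.l2_lambda * float(np.sum(params[k] ** 2))
        return pen

    # ------------------------------------------------------------- backward
    def _backward(self, params, conv, cache, r, y, lfp, mua, stage, warm_mask):
        R, T = r.shape
        n = float(warm_mask.sum()) * R  # matches the masked-loss normalizer
        if self.loss == "poisson":
            dr = (1.0 - y / (r + _EPS)) / n
        else:
            dr = 2.0 * (r - y) / n
        dr = dr * warm_mask[None, :]
        pos, x, xe, g, e = (cache[k] for k in ("pos", "x", "xe", "g", "e"))
        # through N(x) = g x^e
        dx = np.zeros_like(x)
        xp = np.where(pos, x, 1.0)
        dx[pos] = (dr * g * e * xe / xp)[pos]
        grads = {}
        if stage == 2:
            grads["g"] = float((dr * xe)[pos].sum())
            grads["exp"] = float((dr * g * xe
                                  * np.log(np.maximum(xp, _EPS)))[pos].sum())
        mode = self.combine_mode
        r_stim, m = cache["r_stim"], cache["m"]
        if mode == "additive":
            dr_stim = dx.sum(axis=0)
            dm = dx
        elif mode == "multiplicative":
            dr_stim = (dx * (1.0 + m)).sum(axis=0)
            dm = dx * r_stim[None, :]
        else:  # divisive
            den = cache["den"]
            live = den > 1e-6
            dr_stim = (dx / den).sum(axis=0)
            dden = np.where(live, -dx * r_stim[None, :] / den ** 2, 0.0)
            grads["semi_sat"] = float(dden.sum())
            grads["state_gain"] = float((dden * m).sum())
            dm = dden * float(params["state_gain"])
        if "f_lfp" in params:
            grads["f_lfp"] = (np.einsum("rt,rtwc->cw", dm, lfp)
                              + 2.0 * self.l2_lambda * params["f_lfp"])
        if "f_mua" in params:
            grads["f_mua"] = (np.einsum("rt,rtwc->cw", dm, mua)
                              + 2.0 * self.l2_lambda * params["f_mua"])
        # stimulus pathway
        a, u, wmap = cache["a"], cache["u"], cache["wmap"]
        da = dr_stim[:, None, None] * wmap[None, :, :]
        wgrad = np.einsum("t,thw->hw", dr_stim, a)
        alpha = float(params["alpha"])
        du = da * np.where(u > 0, 1.0, alpha)
        grads["alpha"] = float((da * np.minimum(u, 0.0)).sum())
        grads["c"] = conv.grad_c(du)
        # mass-normalized Gaussian map (trained as mu, log sigma, log gain)
        H, W = wmap.shape
        gx, gy = self._grid(H, W)
        sigma, G, S, rho = (cache[k] for k in ("sigma", "G", "S", "rho"))
        wg = wgrad * wmap
        A = float(wg.sum())
        grads["log_gain"] = A
        px = (gx - params["mu"][0]) / sigma ** 2
        py = (gy - params["mu"][1]) / sigma ** 2
        grads["mu"] = np.array([
            float((wg * px).sum()) - A * float((G * px).sum()) / S,
            float((wg * py).sum()) - A * float((G * py).sum()) / S,
        ])
        grads["log_sigma"] = (float((wg * rho).sum())
                              - A * float((G * rho).sum()) / S) / sigma ** 2
        return grads

    def _project(self, params):
        params["alpha"] = np.float64(np.clip(params["alpha"], -1.0, 1.0))
        params["g"] = np.float64(max(float(params["g"]), 1e-6))
        params["exp"] = np.float64(max(float(params["exp"]), 1e-6))
        if "semi_sat" in params:
            params["semi_sat"] = np.float64(max(float(params["semi_sat"]), 1e-6))
        # keep sigma within a sane numeric range
        params["log_sigma"] = np.float64(np.clip(params["log_sigma"], -3.0, 8.0))

    # ----------------------------------------------------------- stage loop
    def _run_stage(self, params, conv, y, lfp, mua, val, stage):
        trainable = [k for k in params
                     if not (stage == 1 and k in ("g", "exp"))]
        opt = _Adam(trainable, self.learning_rate)
        warm = np.ones(conv.T)
        warm[:self.n_lags - 1] = 0.0  # zero-padded history excluded from loss
        warm_val = None
        if val is not None:
            warm_val = np.ones(val[0].T)
            warm_val[:self.n_lags - 1] = 0.0
        best_loss, best_epoch, best_params = np.inf, -1, None
        train_curve, val_curve = [], []
        for epoch in range(self.max_epochs):
            r, cache = self._forward(params, conv, lfp, mua, y.shape[0], stage)
            data_loss = self._masked_loss(r, y, warm)
            loss = data_loss + self._penalty(params)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (stage {stage})")
            grads = self._backward(params, conv, cache, r, y, lfp, mua,
                                   stage, warm)
            opt.step(params, {k: grads[k] for k in trainable if k in grads})
            self._project(params)
            train_curve.append(loss)
            if val is not None:
                vconv, yv, lfpv, muav = val
                rv, _ = self._forward(params, vconv, lfpv, muav,
                                      yv.shape[0], stage)
                monitor = self._masked_loss(rv, yv, warm_val)
            else:
                monitor = data_loss
            val_curve.append(monitor)
            if monitor < best_loss - 1e-12:
                best_loss, best_epoch = monitor, epoch
                best_params = {k: np.copy(v) for k, v in params.items()}
            if epoch - best_epoch >= self.patience:
                break
        if best_params is not None:
            params = best_params
        self.history_.append({
            "stage": stage,
            "train_loss": np.asarray(train_curve),
            "monitor_loss": np.asarray(val_curve),
            "best_epoch": best_epoch,
            "n_epochs": len(train_curve),
        })
        return params

    def _masked_loss(self, r, y, mask):
        w = mask[None, :]
        n = float(w.sum() * r.shape[0])
        if self.loss == "poisson":
            return float((w * (r - y * np.log(r + _EPS))).sum() / n)
        return float((w * (r - y) ** 2).sum() / n)

    # --------------------------------------------------------------- output
    def _store(self, params, shape, normalized=True):
        self.filter_c_ = params["c"]
        self.alpha_ = float(params["alpha"])
        self.map_center_ = (float(params["mu"][0]), float(params["mu"][1]))
        self.map_sigma_ = float(np.exp(params["log_sigma"]))
        gain = float(np.exp(params["log_gain"]))
        if normalized:
            # training uses a mass-normalized map; store the plain-Gaussian
            # equivalent so rendered maps and restorations are standalone
            gx, gy = self._grid(*shape)
            rho = ((gx - params["mu"][0]) ** 2 + (gy - params["mu"][1]) ** 2)
            gain /= float(np.exp(-rho / (2 * self.map_sigma_ ** 2)).sum())
        self.map_gain_ = gain
        self.f_lfp_ = params.get("f_lfp")
        self.f_mua_ = params.get("f_mua")
        self.gain_ = float(params["g"]) if self.two_stage else 1.0
        self.exponent_ = float(params["exp"]) if self.two_stage else 1.0
        self.semi_saturation_ = float(params.get("semi_sat", 1.0))
        self.state_gain_ = float(params.get("state_gain", 1.0))
        self.grid_shape_ = shape
        stim = StimulusPathwayParams(self.filter_c_, self.alpha_,
                                     self.map_center_, self.map_sigma_,
                                     self.map_gain_)
        state = None
        if self.f_lfp_ is not None or self.f_mua_ is not None:
            state = StatePathwayParams(self.f_lfp_, self.f_mua_,
                                       l2_lambda=self.l2_lambda)
        mode = "powerlaw_stage" if self.two_stage else "relu_stage"
        self.params_ = EncodingModelParams(
            stim=stim, state=state,
            out_nl=OutputNonlinearity(self.gain_, self.exponent_, mode),
            combine_mode=self.combine_mode, variant=self.variant,
            semi_saturation=self.semi_saturation_, state_gain=self.state_gain_)

    def predict(self, X, *, lfp_segments=None, mua_segments=None):
        """Predicted firing rate per frame; (T,) or (trials, T) with state."""
        from .model import combine, forward_stimulus
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        r_stim = forward_stimulus(self.params_.stim, X)
        squeeze = True
        if self.params_.state is None or (lfp_segments is None
                                          and mua_segments is None):
            m = np.zeros((1, X.shape[0]))
        else:
            segs = []
            for s in (lfp_segments, mua_segments):
                if s is None:
                    segs.append(None)
                    continue
                s = np.asarray(s, dtype=float)
                if s.ndim == 3:
                    s = s[None]
                else:
                    squeeze = False
                segs.append(s)
            lfp, mua = segs
            R = max(s.shape[0] for s in segs if s is not None)
            m = np.zeros((R, X.shape[0]))
            if self.f_lfp_ is not None and lfp is not None:
                m += np.einsum("rtwc,cw->rt", lfp, self.f_lfp_)
            if self.f_mua_ is not None and mua is not None:
                m += np.einsum("rtwc,cw->rt", mua, self.f_mua_)
        out = np.stack([
            combine(r_stim, mi, np.zeros_like(mi), self.params_.out_nl,
                    mode=self.combine_mode,
                    semi_saturation=self.semi_saturation_,
                    state_gain=self.state_gain_)
            for mi in m])
        return out[0] if (squeeze and out.shape[0] == 1) else out
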