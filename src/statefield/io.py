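"""Serialization: HDF5 for arrays and fitted models, CSV for event tables,
JSON for metric records and filter provenance."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signals import BroadbandRecording, LFPChannelSet, MUAEventSeries

__all__ = [
    "save_recording", "load_recording",
    "save_lfp", "load_lfp",
    "save_events", "load_events",
    "save_spike_table", "load_spike_table",
    "save_model", "load_model",
    "save_json", "load_json",
]


def save_recording(path, rec: BroadbandRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.create_dataset("fs", data=rec.fs)
        if rec.channel_depths is not None:
            f.create_dataset("channel_depths", data=rec.channel_depths)


def load_recording(path) -> BroadbandRecording:
    with h5py.File(path, "r") as f:
        depths = f["channel_depths"][()] if "channel_depths" in f else None
        return BroadbandRecording(f["samples"][()], float(f["fs"][()]),
                                  channel_depths=depths)


def save_lfp(path, lfp: LFPChannelSet) -> None:
    """LFP arrays to HDF5 with the filter provenance as a JSON sidecar."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=lfp.samples)
        f.create_dataset("fs", data=lfp.fs_down)
    sidecar = Path(path).with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(lfp.provenance, indent=2))


def load_lfp(path) -> LFPChannelSet:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        fs = float(f["fs"][()])
    sidecar = Path(path).with_suffix(".provenance.json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return LFPChannelSet(samples, fs, provenance=prov)


def save_events(path, mua: MUAEventSeries) -> None:
    """Ragged per-channel event times as one HDF5 dataset per channel."""
    with h5py.File(path, "w") as f:
        f.attrs["threshold_sd"] = mua.threshold_sd
        f.attrs["source_fs"] = mua.source_fs
        for ch, times in enumerate(mua.event_times):
            f.create_dataset(f"channel_{ch:03d}", data=times)


def load_events(path) -> MUAEventSeries:
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f if k.startswith("channel_"))
        times = [f[k][()] for k in keys]
        return MUAEventSeries(times, threshold_sd=float(f.attrs["threshold_sd"]),
                              source_fs=float(f.attrs["source_fs"]))


def save_spike_table(path, ids, times) -> None:
    """Two-column CSV (id, time_s) for spike times or frame onsets."""
    pd.DataFrame({"id": ids, "time_s": times}).to_csv(path, index=False)


def load_spike_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(path, est) -> None:
    """Fitted EncodingRegressor parameters to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["variant"] = est.variant
        f.attrs["combine_mode"] = est.combine_mode
        g = f.create_group("stim")
        g.create_dataset("filter_c", data=est.filter_c_)
        g.create_dataset("alpha", data=est.alpha_)
        g.create_dataset("map", data=np.array([est.map_center_[0],
                                               est.map_center_[1],
                                               est.map_sigma_, est.map_gain_]))
        s = f.create_group("state")
        if est.f_lfp_ is not None:
            s.create_dataset("f_lfp", data=est.f_lfp_)
        if est.f_mua_ is not None:
            s.create_dataset("f_mua", data=est.f_mua_)
        f.create_dataset("out_nl", data=np.array([est.gain_, est.exponent_]))


def load_model(path):
    """Rebuild a fitted EncodingRegressor from HDF5 (predict-ready)."""
    from .estimator import EncodingRegressor

    with h5py.File(path, "r") as f:
        est = EncodingRegressor(variant=str(f.attrs["variant"]),
                                combine_mode=str(f.attrs["combine_mode"]))
        c = f["stim/filter_c"][()]
        mu0, mu1, sigma, gain = f["stim/map"][()]
        params = {
            "c": c, "alpha": np.float64(f["stim/alpha"][()]),
            "mu": np.array([mu0, mu1]),
            "log_sigma": np.float64(np.log(sigma)),
            "log_gain": np.float64(np.log(gain)),
            "g": np.float64(f["out_nl"][()][0]),
            "exp": np.float64(f["out_nl"][()][1]),
        }
        if "state/f_lfp" in f:
            params["f_lfp"] = f["state/f_lfp"][()]
        if "state/f_mua" in f:
            params["f_mua"] = f["state/f_mua"][()]
        est.n_lags = c.shape[0]
        est.kernel_size = c.shape[1]
        est.history_ = []
        est._store(params, None, normalized=False)
    return est


def save_rf_montage(path, rf, ncols: int | None = None) -> None:
    """Restored-RF planes as a one-row-per-lag PNG montage."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    planes = rf.rf if hasattr(rf, "rf") else np.asarray(rf)
    L = planes.shape[0]
    ncols = ncols or L
    vmax = np.abs(planes).max() or 1.0
    fig, axes = plt.subplots(1, ncols, figsize=(2 * ncols, 2.2))
    axes = np.atleast_1d(axes)
    for tau in range(ncols):
        ax = axes[tau]
        ax.imshow(planes[tau], cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_title(f"-{tau * 13.333:.1f} ms", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_metrics_csv(path, records: list[dict]) -> None:
    """Batch per-neuron metric export, one row per neuron."""
    pd.DataFrame(records).to_csv(path, index=False)


def save_json(path, record: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(record, indent=2, default=default))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
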