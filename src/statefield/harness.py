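"""Desk-scale reproducibility harness.

Builds synthetic populations with graded cortical-state coupling, runs the
model ladder on them, and summarizes parameter recovery and the
population-level relationships between trial-to-trial variability (VR),
predictive performance (VAF) and the state pathways' contribution
(VAF improvement, VAF_ongoing). Problem sizes are deliberately desk-scale:
a 12-neuron population on a 12x12 grid with 3 training ensembles, and a
single-neuron recovery run on a 16x16 grid with 10 ensembles.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .evaluation import vaf, vaf_ongoing
from .metrics import variability_ratio
from .model import restore_rf
from .synthetic import (_spectral_correlation, make_ground_truth,
                        make_neuron_dataset, reference_lfp_psd)
from .training import FitConfig, model_ladder

__all__ = ["recovery_run", "build_population", "evaluate_population",
           "population_summary"]

#: graded state-coupling gains across the population (relative to the
#: stimulus drive's unit SD) and firing-rate targets (spikes/s). The
#: smallest nonzero grade (0.6) is set at the desk-scale detection floor:
#: a weaker state drive contributes under ~1/3 of the stimulus variance and
#: is not resolvable from 3 training ensembles under Poisson noise, so it
#: would only probe estimator noise rather than the coupling ladder.
POPULATION_GAINS = (0.0, 0.0, 0.6, 0.7, 0.85, 1.0, 1.15, 1.3, 1.5, 1.7,
                    1.95, 2.2)
POPULATION_RATES = (60.0, 25.0, 30.0, 25.0, 20.0, 25.0, 15.0, 20.0, 15.0,
                    12.0, 10.0, 20.0)


def recovery_run(seed: int, grid: int = 16, n_train_ensembles: int = 10,
                 n_reps: int = 20, coupling_gain: float = 1.0,
                 target_rate_hz: float = 30.0, n_lfp_channels: int = 1,
                 max_epochs: int = 1200, patience: int = 75) -> dict:
    """Fit an LFP-coupled synthetic neuron; report parameter recovery.

    Returns restored-RF correlation, PReLU alpha error, LFP-filter spectral
    correlation (input-PSD-weighted, 0-100 Hz) and test VAF. The stated
    SNR: state drive as strong as the stimulus drive (coupling 1.0),
    30 spikes/s, one LFP channel, no MUA coupling. This is the well-posed
    probe of the fitting machinery: with several collinear channels, or
    LFP and MUA both slaved to the same latent state, the split of the
    state drive across inputs is not identifiable at desk scale, so a
    multi-input probe would measure attribution ambiguity rather than
    estimator quality (the population ladder exercises the multi-channel
    and MUA pathways).
    """
    gt = make_ground_truth(seed, grid=grid, coupling_gain=coupling_gain,
                           target_rate_hz=target_rate_hz,
                           n_lfp_channels=n_lfp_channels, mua_weight=0.0)
    data = make_neuron_dataset(gt, seed=seed + 1,
                               n_train_ensembles=n_train_ensembles,
                               n_reps=n_reps)
    # LFP-coupled ground truth fitted with the all-LFP-channel variant:
    # with LFP and MUA both slaved to the same latent state, drive
    # attribution between the two pathways is not identifiable, so the
    # recovery probe couples through LFP alone (the ladder run exercises
    # the MUA pathway)
    cfg = FitConfig(seed=seed + 2, variant="m2", max_epochs=max_epochs,
                    patience=patience, learning_rate=3e-3, l2_lambda=1e-3)
    from .training import fit_model
    est, _ = fit_model(data, cfg)
    rf_true = gt.restored_rf().rf
    rf_fit = restore_rf(est.params_.stim, shape=(grid, grid)).rf
    a = rf_true.ravel() - rf_true.mean()
    b = rf_fit.ravel() - rf_fit.mean()
    den = np.sqrt((a @ a) * (b @ b))
    pred = est.predict(data.stim_test, lfp_segments=data.lfp_test)
    return {
        "rf_correlation": float(a @ b / den) if den else np.nan,
        "alpha_true": gt.stim.prelu_alpha,
        "alpha_fit": est.alpha_,
        "alpha_error": float(abs(est.alpha_ - gt.stim.prelu_alpha)),
        "lfp_filter_spectral_correlation":
            _spectral_correlation(gt.state.f_lfp, est.f_lfp_,
                                  weights=reference_lfp_psd(seed + 5)),
        "test_vaf_m2": float(vaf(data.y_test, pred)),
        "n_frames_train": int(data.y_train.size),
    }


def build_population(seed: int, n_neurons: int = 12, grid: int = 12,
                     kernel: int = 7, n_lfp_channels: int = 3,
                     n_train_ensembles: int = 3, n_reps: int = 10):
    """Synthetic neurons spanning graded coupling and firing rates."""
    pop = []
    for i in range(n_neurons):
        gain = POPULATION_GAINS[i % len(POPULATION_GAINS)]
        rate = POPULATION_RATES[i % len(POPULATION_RATES)]
        gt = make_ground_truth(seed + 7 * i, grid=grid, kernel=kernel,
                               coupling_gain=gain, target_rate_hz=rate,
                               n_lfp_channels=n_lfp_channels)
        data = make_neuron_dataset(gt, seed=seed + 7 * i + 1,
                                   n_train_ensembles=n_train_ensembles,
                                   n_reps=n_reps)
        pop.append((gt, data))
    return pop


def evaluate_population(pop, seed: int, max_epochs: int = 300,
                        l2_lambda: float = 1e-3) -> list[dict]:
    """Base and full-model (m3) ladder per neuron, with VR and VAF_ongoing."""
    rows = []
    for i, (gt, data) in enumerate(pop):
        cfg = FitConfig(seed=seed + 13 * i, max_epochs=max_epochs,
                        learning_rate=3e-3, l2_lambda=l2_lambda)
        out = model_ladder(data, cfg, variants=("base", "m3"))
        base, full = out["models"]["base"], out["models"]["m3"]
        r_base = base.predict(data.stim_test)
        r_full = full.predict(data.stim_test, lfp_segments=data.lfp_test,
                              mua_segments=data.mua_test)
        with np.errstate(invalid="ignore"):
            vo = vaf_ongoing(data.y_test, r_full, r_base) \
                if gt.coupling_gain > 0 else np.nan
        rows.append({
            "coupling_gain": gt.coupling_gain,
            "target_rate_hz": gt.target_rate_hz,
            "vr": float(variability_ratio(data.y_reg).vr),
            "vaf_base": float(out["vaf"]["base"]),
            "vaf_m3": float(out["vaf"]["m3"]),
            "vaf_improvement": float(out["vaf"]["m3"] - out["vaf"]["base"]),
            "vaf_ongoing": float(vo) if np.isfinite(vo) else None,
            "low_base_vaf": out["low_base_vaf"],
            "unresponsive": out["unresponsive"],
        })
    return rows


def population_summary(rows: list[dict]) -> dict:
    """Sign-level population relationships (Spearman rank correlations)."""
    vr = np.array([r["vr"] for r in rows])
    base = np.array([r["vaf_base"] for r in rows])
    imp = np.array([r["vaf_improvement"] for r in rows])
    coupled = [r for r in rows if r["coupling_gain"] > 0]
    vo_pairs = [(r["vaf_improvement"], r["vaf_ongoing"]) for r in coupled
                if r["vaf_ongoing"] is not None]
    out = {
        "n_neurons": len(rows),
        "vr_min": float(vr.min()),
        "vr_max": float(vr.max()),
        "spearman_vr_vaf_base": float(spearmanr(vr, base).statistic),
        "spearman_vr_vaf_improvement": float(spearmanr(vr, imp).statistic),
        "n_coupled": len(coupled),
        "n_coupled_improved": int(sum(r["vaf_improvement"] >= 0
                                      for r in coupled)),
    }
    if len(vo_pairs) >= 3:
        a, b = zip(*vo_pairs)
        out["spearman_improvement_vaf_ongoing"] = \
            float(spearmanr(a, b).statistic)
    return out
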