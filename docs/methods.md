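# Methods

## The model

`statefield` fits a two-pathway encoding model of single-neuron spiking in
early visual cortex. The stimulus-driven pathway is a compact
linear–nonlinear cascade: a cropped, downsampled luminance movie
`s[x, y, t]` (30×30 grid by convention, 75 Hz frame rate) is convolved with
a spatiotemporal filter `c[τ, j, k]` (L = 6 frame lags, 13.333 ms each —
spanning 0 to −66.7 ms, the range over which cortical RFs peak and
reverse); the convolution image passes through a parametric rectifier
(PReLU with slope α ∈ [−1, 1] for negative inputs: α → 1 behaves like a
linear, simple-type cell, α → 0 like a rectifying, complex-type cell); and
an isotropic Gaussian map `w` with center (µx, µy), width σ and positive
gain reads out where in space the filter drives the cell:

    r_stim[t] = Σ_{x,y} w[x,y] · PReLU_α( Σ_{j,k,τ} c[τ,j,k] · s[x−j, y−k, t−τ] )

Two cortical-state pathways add per-frame modulatory drives: 150-tap
temporal filters applied to onset-anchored LFP segments (one filter per
channel; 150 samples at the 10×-decimated rate ≈ 50 ms from frame onset)
and to binarized, 10:1 sum-binned MUA event trains from two nearby
channels. The combined drive passes through a rectified power law
`N(x) = g·x^exp` (x > 0, else 0):

    r_est = N(r_stim + m_LFP + m_MUA)

Additive combination is the default; multiplicative
(`N(r_stim · (1 + m))` — the state modulates gain around unity so zero
filters reduce to the base model) and divisive
(`N(r_stim / (σ_half + γ·m))`, σ_half > 0 trainable with a 1e-6 floor)
variants are implemented behind the same interface. The model ladder is:
`base` (stimulus only), `m1` (one nearby LFP channel), `m2` (all LFP
channels except the neuron's own), `m3` (m2 plus two MUA channels).

Spatial convolution is zero-padded with the kernel anchored at index (0,0)
(full convolution cropped to the leading H×W block); all grids are 0-based.
The first L−1 frames have zero-padded stimulus history and are excluded
from training loss and evaluation.

## Signal conditioning

LFP: zero-phase Kaiser-window FIR low-pass (pass 100 Hz, stop 120 Hz,
0.1 dB ripple, 60 dB attenuation; zero phase via one symmetric
forward–backward kernel), zero-phase 2nd-order Butterworth band-stop with
half-power at 59/61 Hz, then 10× decimation. The state pathway re-applies
the low-pass and notch at the decimated rate before segmentation, matching
the pathway-specific conditioning order. MUA: zero-phase Kaiser FIR
high-pass (pass 600 Hz, stop 550 Hz), events at |z| > 5 SD per channel
(full-trace SD, not a robust estimator), one event per threshold excursion
timed at the first crossing, with a 1 ms dead time merging the multiple
crossings of a multiphasic spike waveform. Spike-waveform spillover into
neighbouring MUA channels is removed when events coincident with the sorted
neuron's spikes (±0.5 ms by default) exceed 10% of the channel's events.
Band-limited LFP phases (δ 0.5–4, θ 4–7.5, α 7.5–12.5, β 12.5–30,
γ 30–100 Hz) use zero-phase Kaiser FIR band-passes (transition widths
0.5/0.5/0.5/2/5 Hz — a design choice trading filter length against
selectivity at the lowest bands) and the analytic-signal angle.

## Statistics

* **VR** = 1 − mean over trials of the squared Pearson correlation between
  each trial and the mean of the remaining n−1 trials. Degenerate
  (zero-variance) trials contribute R² = 0 with a flag: a silent trial is
  maximally unreliable. VR treats anti-correlated trials as reliable
  (squaring) — a documented property of the statistic.
* **PLS** = |mean unit phasor| at spike-time band phases, nearest-sample
  phase lookup (error bounded by the sample interval).
* **GFI** = SD/mean of the channel-averaged 100 ms-binned MUA rate over a
  blank interval; sample SD (ddof = 1).
* **SI** = P_low/(P_low + P_high) per spectrogram bin (30 s Hann windows,
  83.33% overlap; P_low 0.5–15 Hz and P_high 15–100 Hz by trapezoid
  integration of the PSD; the 15 Hz boundary sample is a shared quadrature
  endpoint). Absolute band powers depend on the PSD normalization; SI does
  not.
* **VAF** = squared Pearson correlation × 100 between observed and
  predicted responses, concatenated across trials (state-pathway
  predictions are trial-specific; the base model's single prediction is
  tiled). **VAF_ongoing** correlates the per-trial residual from the trial
  mean with the full-minus-base prediction difference.
* **RF quality Z**: restored RF (filter convolved with map per lag), z-map
  at the peak lag (lag of maximal spatial variance, overridable) scaled by
  the lag-0 plane's SD, Z = population variance (ddof = 0) of the z-map.

## Fitting

Parameters are optimized by full-batch Adam (step 1e-3 by default; the
harness uses 3e-3) with analytically derived gradients — the model is a few
hundred parameters, so no autodiff framework is needed; all gradients are
finite-difference-verified in the test suite. The objective is mean squared
error between the predicted rate and binned counts (Poisson negative
log-likelihood is available as a config option). The training protocol:

1. **Stage 1**: output nonlinearity fixed to a ReLU; filter from a Glorot
   normal draw, α = 0.5, map centered with σ = image side, state filters
   from zero (the full model starts at the base model and earns its state
   pathway from the data).
2. **Stage 2**: the spatiotemporal filter warm-starts from stage 1; all
   other parameters re-initialize as in stage 1; the output nonlinearity
   (g, exp), initialized at (1, 1), is trainable.

L2 regularization applies to the LFP/MUA temporal filters only, with λ
either fixed or selected on the regularization split from a logarithmic
grid {1e-4, 1e-3, 1e-2}. Early stopping monitors the regularization-split
loss with patience 50 (harness: 50–100) and restores the best-epoch
weights. Fits are bit-deterministic given the seed.

Internally the Gaussian map is trained in mass-normalized form
(gain · Gaussian / ΣGaussian): with a plain Gaussian, shrinking σ drags
the output scale down with it, coupling two parameters along a narrow
valley; normalization removes that first-order coupling. Fitted attributes
convert back to the plain-Gaussian parameters of the model contract. The
map center and log-width are clipped to a sane numeric range; α is clipped
to [−1, 1] and (g, exp) to ≥ 1e-6 after each step.

Three-pass cropping localizes the RF on full-resolution stimuli: fit the
base model on the full frame downsampled to the model grid, crop a square
window at the fitted map center ± 3σ (converted to source pixels, minimum
side 120 px, clamped to the frame), re-downsample and refit; three passes.
A degenerate map (σ ≥ 1.5× the grid) falls back to the full frame with a
warning; a merely broad map still carries a usable center, and an
overestimated σ clamps the window to the frame. At desk-scale data sizes
with 1/f stimuli the fitted width typically is such an overestimate, so
the crop's verifiable contracts there are the pass structure, center
containment and clamping; actual zooming emerges at the data sizes of
real recording sessions.

The single-precision FFT convolution path (precomputed stimulus spectra;
complex64) keeps epochs at tens of milliseconds; the fit is
noise-dominated far above float32 resolution, and the float64 path remains
available for verification.

## Synthetic data

The generator makes every stage testable without recordings, and defines
what passing tests show:

* **Stimulus**: 1/f-amplitude noise frames (mean-subtracted, RMS contrast
  40 grey levels, clipped to 8-bit range), 375 frames per 5 s trial at
  75 Hz — the second-order statistics of natural images without their
  higher-order structure. Consequences of 1/f correlations are real and
  intentional: neighbouring stimulus positions are correlated, which is
  exactly why a Gaussian map wider than the true one can mimic a localized
  RF (see below).
* **Latent state** s(t) ∈ [0, 1]: a smoothed two-state telegraph process
  (exponential dwells ~0.4 s clipped to 0.1–1 s — up/down-state
  timescales) mixed 70/30 with a slow drift. The LFP's 0.5–15 Hz component
  scales as (0.1 + 0.9·s), a shared 2.5 Hz oscillation scales with s, the
  15–100 Hz component scales as (1 − 0.7·s), and channels share these with
  channel-specific pink noise (amplitude 0.15); MUA is inhomogeneous
  Poisson at 40·(0.15 + 0.85·s) events/s per channel. These constants were
  set so that SI and GFI computed by the package visibly track s(t) — the
  qualitative structure the generator exists to emulate; no quantitative
  state→LFP mapping is claimed.
* **Neuron**: a Gabor-profile filter under a biphasic temporal profile
  (peak at −26.7 ms, reversal by −66.7 ms, near-zero at lag 0), true
  α = 0.6, Gaussian map with σ = grid/4, rectified power law (exp = 1.1).
  The map width reflects post-crop geometry: the cropping pass zooms the
  model grid onto the RF, so the envelope spans a large fraction of the
  frame. (With 1/f stimuli, a much smaller envelope is weakly identifiable
  — a broad map over correlated inputs imitates it — which is a property
  of the estimation problem, not of this implementation.) The stimulus
  drive is calibrated to unit SD; state filters (smooth per-channel
  band-emphasis shapes for LFP, a biphasic bump for MUA) are scaled so the
  state drive's SD equals the coupling gain; the output gain is calibrated
  to a target mean rate. Spikes are per-trial Poisson draws with the
  stimulus frozen and the state redrawn per trial, so all trial-to-trial
  structure flows through the state plus Poisson noise. A rate cap rejects
  runaway configurations.

What passing recovery tests do **not** show about real data: real neurons
are not in the model family, natural images have higher-order structure,
real LFP/state coupling is unknown, and anesthesia-level nonstationarities
are not modelled.

## Harness problem sizes and identifiability

Desk-scale sizes keep every run on one CPU in minutes: the single-neuron
recovery run uses a 16×16 grid, 10 training ensembles of 375 frames,
20-repeat regularization/test splits, one LFP channel coupled at gain 1.0
(state drive as strong as the stimulus drive — the regime of
high-variability neurons) and 30 spikes/s; the population ladder uses 12
neurons on a 12×12 grid, 3 training ensembles, 10 repeats, graded coupling
gains 0 → 2.2 and rates 10–60 spikes/s. The smallest nonzero coupling
grade (0.6, paired with higher firing rates for the weaker grades) sits at
the desk-scale detection floor: a state drive contributing under about a
tenth of the response variance at low rates is not resolvable from 3
ensembles under Poisson noise, and would probe estimator noise rather than
the coupling ladder. At these sizes the population spans VR ≈ 0.55–0.99;
pushing VR toward the low end requires higher sustained rates than the
population uses (the generator itself reaches VR ≈ 0.25 at ~150 spikes/s
with zero coupling).

Two identifiability facts shape the recovery harness, and they are
properties of the estimation problem, not of this implementation. First,
the 150-tap state filters are constrained only through onset-anchored
segments of a <100 Hz signal, so the segment covariance has an effective
rank of roughly 2 × bandwidth × window ≈ 10: most tap-space directions are
near-null, and the recovery comparison therefore correlates filter
amplitude spectra weighted by the input PSD (a faithful estimate is only
possible where the input carries power; for a pink LFP the power at 35 Hz
is ~2% of that at 5 Hz). Second, the split of a shared state drive across
several collinear LFP channels — or between the LFP and MUA pathways, both
slaved to the same latent state — is not identifiable at desk scale. The
recovery probe therefore couples one neuron through one LFP channel
(fitted with the all-channels variant); the multi-channel and MUA pathways
are validated functionally through the population ladder, where their
contribution to held-out prediction is the measured quantity.

## Known limitations

* The training objective (MSE), optimizer and learning rate are package
  choices; the protocol (stages, init, penalty placement, early stopping)
  is the contract.
* Divisive-variant training clips its denominator at 1e-6 for stability;
  the `combine` contract rejects configurations whose denominator crosses
  zero.
* Map anisotropy is not modelled (isotropic Gaussian, chosen for
  parsimony).
* `segment_mua` binarizes events on the fine grid: two events in the same
  raw sample collapse (at 30 kHz this requires sub-33 µs coincidence on
  one channel).
* VAF is computed on concatenated per-trial test responses; the
  trial-averaged alternative is available by passing averaged counts.
* Early-stopped state-filter estimates are shrunk toward zero with an
  input-power-weighted bias (the held-out-optimal amount of shrinkage at
  desk-scale SNR); their overall scale should not be read as coupling
  strength. Held-out prediction (VAF improvement) is the calibrated
  measure of state coupling.
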