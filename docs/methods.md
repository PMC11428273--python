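# Methods

`boldcast` forecasts ROI-averaged resting-state BOLD signals and uses the
forecasts to prolong short fMRI scans. This note documents the model, its
assumptions, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Problem setting

A subject is a matrix `Y ∈ R^{m×T}` of m region time series sampled every TR
seconds. A sliding window of length `L = D + H` cuts each series into a
history block (all m regions, D timepoints) and a horizon (the target
region's next H values). The model `f̂` maps the multivariate history to the
target's horizon; every region of the network takes its turn as the target,
with the remaining regions as auxiliary inputs. Forecasting is done per
subject, per target region and per frequency band: BOLD dynamics are
individual enough that sharing one model across subjects is a documented
extension, off by default.

## Frequency-specific decomposition (VMD)

Raw BOLD is non-stationary; its low-frequency band (~0.01–0.05 Hz) carries
the reproducible connectome signal. Each region's series is decomposed by
variational mode decomposition into K band-limited modes u_k with center
frequencies ω_k, obtained by ADMM on the augmented Lagrangian of the
bandwidth-minimization problem: per sweep, a Wiener-filter update of each
mode spectrum around its current center, a re-centering of ω_k at the
spectral center of mass, and (for τ > 0) dual ascent on the reconstruction
multiplier. Modes with center frequency below `f_max = 0.05 Hz` — typically
the two lowest of K = 4 — are kept; each is forecast separately and the
forecasts are superimposed.

Numerical choices:

* **Boundary handling.** The series is mirror-extended by T/2 on each side
  before the frequency-domain iteration and trimmed afterwards; this is
  standard VMD practice to suppress edge ringing of the Wiener filters.
* **Defaults.** K = 4, α = 2000, τ = 0 (noise-robust; exact reconstruction
  relaxed), tol = 1e-7 on the summed relative mode change, max 500 sweeps.
  α, τ and the tolerance are free parameters of the method; the defaults are
  the package's own choices and are exposed in `VmdConfig`.
* **α convention.** The mode update uses `1/(1 + α(ω−ω_k)²)` with ω in
  cycles/sample, the convention of the reference VMD implementations; a
  factor of 2 on α relative to other writings of the update is absorbed into
  the α scale.
* **ω initialization.** Uniform spacing over [0, 0.5) cycles/sample by
  default; zero and seeded-random initializations exist for robustness
  checks.
* **Units.** Center frequencies are stored in cycles/sample and converted to
  Hz (÷ TR) only at reporting boundaries.
* **Look-ahead.** Decomposition runs on the full series before the
  chronological split, mirroring the staged design it implements; a VMD mode
  at timepoint t is influenced by later samples, so the split is clean for
  the forecaster but not for the decomposition itself. At the scales tested
  this is a second-order effect, but it is a real caveat for deployment.

## Windowing and normalization

Each (region, IMF) series is max–min normalized, `ȳ = (y − y_min)/(y_max −
y_min)`. The scalers are fitted on the first 70% of timepoints (the training
era) and applied to the whole series, so validation/test ranges never leak
into training; forecasts may therefore leave [0, 1] slightly, which the
inverse transform handles. Windows use stride 1 (maximizing training data)
and D = 2H by default; the history length is a tunable, not a published
constant. The 7:2:1 train/validation/test split is chronological — earliest
windows train, latest test. A random-by-window split is available behind a
flag for comparison but leaks future timepoints into training and is not the
default.

## Networks

**Generator** — dual attention followed by a GRU encoder–decoder:

1. *Temporal attention*: a 1×m convolution mixes regions at each timestep,
   then a CBAM block (channel attention: average- and max-pooled channel
   descriptors through a shared 2-layer MLP, summed, sigmoid; spatial
   attention: channel-wise average/max maps through a width-7 convolution,
   sigmoid) gates the features. The CBAM spatial gate is the per-timestep
   weight vector.
2. *Spatial attention*: a D×1 convolution mixes time within each region,
   then CBAM; its channel gate is the per-region attention vector in
   (0,1)^m used for physiological interpretation.
3. *Encoder*: a 1×m region-mixing convolution, a 2-layer GRU (hidden 96 by
   default), and a fully connected bridge (96 nodes) producing the decoder's
   initial top-layer state.
4. *Decoder*: a 2-layer GRU unrolled H steps autoregressively (each step
   consumes the previous prediction) with a linear head per step. The first
   decoder input is the target region's last observed value when the target
   index is configured — the decoder continues the series from its anchor
   rather than reconstructing the absolute level from the encoder state
   alone. The exact decoder wiring is an open design point; this choice is
   the package's own.

**Discriminator** — a window-level 3-layer GRU over the H-length sequence
with a fully connected sigmoid head scoring realness in (0,1). It sees only
the horizon window; conditioning on the history is a config option, off by
default. CBAM reduction ratio 8 and spatial kernel 7 are the customary CBAM
defaults and must satisfy `reduction < m`.

All computation runs on a small reverse-mode autodiff engine
(`boldcast.autodiff`) over float64 numpy arrays: forward passes build a tape
of broadcasted arithmetic, matmuls, gates and reductions; `backward()`
topologically sorts the tape and accumulates gradients. Single-threaded
float64 makes runs bit-reproducible for a fixed seed.

## Loss

The generator objective is

    L_G = λ_ae·L_ae + λ_t·L_t + λ_dis·L_dis + λ_g·L_g,  λ = (50, 3, 1, 1)

* `L_ae`: per-window Euclidean distance ‖y − ŷ‖₂ (unsquared — the loss is
  the distance itself, not MSE), averaged over the batch.
* `L_t` (trend): mean |sign(ŷ increment) − sign(y increment)| over the H
  adjacent pairs, anchored at the last observed value. The single-step sign
  comparison generalizes to the whole horizon by averaging; the value lies
  in [0, 2]. The sign function has zero gradient almost everywhere, so
  optimization uses the surrogate tanh(Δ/ε) with ε = 0.01 on the predicted
  increments while evaluation reports the exact sign form.
* `L_dis` (distribution): |mean(y) − mean(ŷ)| per window. A
  variance-matching term exists behind a flag, off by default; the
  first-moment form is the implemented definition.
* `L_g`: sigmoid cross-entropy of the discriminator's fake-window logits
  against the all-ones label, computed in the stabilized
  `max(a,0) − ab + log(1+e^−|a|)` form.

The discriminator minimizes `sce(D(ŷ), 0) + sce(D(y), 1)`. Batch reduction
is the arithmetic mean over windows for every term.

## Training

Two phases, both Adam (β = 0.9, 0.999) with inverse-time-decay learning rate
`lr(step) = 0.01 / (1 + step/200)`:

1. **Supervised phase**: minimizes `L_s = λ_ae L_ae + λ_t L_t + λ_dis L_dis`.
2. **Joint phase**: alternates one discriminator step with one generator
   step on the full `L_G` (the 1:1 ratio is a choice; the alternation ratio
   is configurable).

Gradients are clipped to global norm 5. The parameters with the best
validation RMSE across both phases are retained (validation selection by
RMSE rather than the full L_s is a choice). NaN loss aborts with a
diagnostic. Epoch counts are configuration: 50 + 50 for full runs, 5 + 5 at
the benchmark scale below. Setting `joint_epochs = 0` reproduces the
no-adversarial-phase ablation; `λ_t = 0` the no-trend-loss ablation, and so
on — the switches change only their designated loss terms, which the test
suite verifies on the logged traces.

## Prolongation

To extend a scan by E timepoints: for each retained IMF, every region's
model receives the last D normalized points of its IMF block and predicts H;
predictions are appended to the history and the rollout repeats (the models'
own outputs become history — autoregressive, so auxiliary-region futures are
their own models' forecasts) until E is covered. Per-region forecasts are
denormalized, summed across IMFs, and concatenated to the original series.
E = H needs exactly one forward pass per (region, IMF).

## Test–retest reliability

The FC matrix is the Pearson correlation of all region pairs. Predicted and
observed series act as two sessions: per FC edge, ICC(2,1) — two-way random
effects, absolute agreement, single measures, the convention of the
test–retest FC literature — is computed across subjects from the two-way
ANOVA mean squares. Grades: poor < 0.40 ≤ fair < 0.60 ≤ good ≤ 0.75 <
excellent; boundary values take the higher grade except 0.75, which is good.
Zero-variance edges are reported as missing (NaN) with a count, not as 0.
The "predicted" session is the original history with its final segment
replaced by the rolled-out forecast (a horizon-only mode exists behind a
flag). Individual-level agreement is the per-region Pearson r between
predicted and observed series. The ICC implementation is vectorized over
edges and is cross-checked against `pingouin.intraclass_corr` (ICC(A,1)) in
the test suite.

## Evaluation metrics

RMSE and MAE on the normalized scale, per window, averaged across windows.
DTW is the minimum cumulative |y_i − ŷ_j| over monotone warping paths
(steps right/down/diagonal), dynamic programming over the full cost matrix,
no warping-window constraint; the DP is verified against exhaustive path
enumeration for short sequences. Whether multi-window DTW should be summed
or averaged is unspecified in general; the package reports the mean.

## Synthetic benchmark

The generator emulates the statistics the method relies on: per region, a
sum of band-limited sinusoids with frequency and phase drawn per (subject,
region, component) from configured bands — defaults 0.008–0.016 Hz and
0.03–0.05 Hz, the low-frequency ranges where the connectome is stable, so
the < 0.05 Hz rule keeps both components — mixed through a coupling matrix
(default: identity plus 0.4 × the average of the other regions, making each
region partially predictable from the rest) plus AR(1) noise (coefficient
0.3, innovation s.d. 0.2) emulating BOLD temporal autocorrelation.
Per-subject frequency/phase jitter provides the between-subject variance a
meaningful ICC needs. A cohort is a pure function of (config, seed).

Not emulated: hemodynamic nonlinearity, scanner drift, motion and
physiological artifacts, spatial structure beyond the linear coupling.
Passing benchmarks therefore demonstrate the machinery — decomposition,
optimization, wiring, statistics — not clinical performance on real scans.

Benchmark scale (chosen to run comfortably on one CPU): 6 regions, 600
timepoints, D = 24, H = 12, hidden width 32, batch 32, 5 + 5 epochs. At this
scale the trained model's test RMSE falls well below the untrained network
and below the repeat-last-value baseline (by up to ~3× on favourable draws;
ten epochs leave the optimizer still descending, so the margin over
persistence varies with the random draw); two same-seed runs reproduce the
validation trace exactly. The prolongation
benchmark extends a 300-timepoint, 4-region subject by 120 points (40% of
the scan length).

## Known limitations

* VMD on the full series introduces the look-ahead described above.
* The trend-loss surrogate gradient (tanh/ε) is a biased estimate of the
  sign objective near ties.
* One model per (subject, region, IMF) scales linearly in all three; no
  parameter sharing or warm-starting is implemented.
* The discriminator never sees the history, so it judges marginal horizon
  realism, not conditional plausibility.
* The autodiff engine is deliberately minimal (no fused kernels, no GPU);
  it is sized for the desk-scale problems above, not for thousands of
  windows at hidden width 96.
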