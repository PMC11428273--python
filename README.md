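# boldcast

Frequency-specific, adversarially trained forecasting of ROI-averaged BOLD
(resting-state fMRI) time series — and prolongation of short scans from the
forecasts.

Short scans limit the reliability of functional-connectivity (FC) analyses.
`boldcast` addresses this by learning to continue each brain region's signal:
it decomposes every region's series into band-limited modes, forecasts the
low-frequency modes that carry the stable connectome signal, and appends the
superimposed forecasts to the scan. It then quantifies whether the
synthesized signal preserves the subject's connectome.

The package is aimed at researchers working with parcellated resting-state
time series (regions × timepoints tables) who want a tested, fully seeded
implementation of this pipeline plus the statistics to audit it — without
any dependence on restricted datasets: every stage is exercised on synthetic
cohorts with the relevant statistical structure.

## Method

For a subject `Y ∈ R^{m×T}` sampled every TR seconds:

1. **Variational mode decomposition** splits each region's series into K
   modes `u_k` with center frequencies `ω_k` (ADMM: Wiener-filter mode
   updates, center-of-mass frequency updates, optional dual ascent on the
   reconstruction constraint). Modes with center frequency < 0.05 Hz
   (typically the lowest two of K = 4) are kept.
2. **Windowing**: each retained mode is max–min normalized and cut into
   sliding windows of D history points (all m regions) and an H-point
   horizon (target region only); windows split 7:2:1 chronologically.
3. **Adversarial forecasting**: the generator — temporal attention (1×m
   conv + CBAM), spatial attention (D×1 conv + CBAM, exposing a per-region
   attention vector), a 2-layer GRU encoder, and a 2-layer GRU decoder
   unrolled H steps — is trained against a 3-layer GRU discriminator under
   the hybrid objective

       L_G = λ_ae‖y−ŷ‖₂ + λ_t·L_trend + λ_dis|E[y]−E[ŷ]| + λ_g·L_adv,

   λ = (50, 3, 1, 1), in a supervised phase (L_s only) followed by a joint
   alternating phase. The trend term compares the sign of adjacent-step
   increments over the horizon.
4. **Prolongation**: each (region, IMF) model predicts from the last D
   points, rolls forward autoregressively to the requested extension, and
   the denormalized per-mode forecasts are superimposed.
5. **Evaluation**: RMSE, MAE and dynamic time warping on the normalized
   scale; test–retest reliability via per-edge ICC(2,1) of FC matrices
   (predicted vs observed sessions) graded poor/fair/good/excellent at
   0.40/0.60/0.75, plus per-subject Pearson agreement.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from boldcast import (GeneratorSpec, SyntheticConfig, TrainConfig, VmdConfig,
                      WindowSpec, decompose_cohort, generate_cohort,
                      persistence_forecast, predict, prepare_task, rmse, fit)

cohort = generate_cohort(SyntheticConfig(n_subjects=1, m=6, T=600, seed=0))
decomp = decompose_cohort(cohort, VmdConfig(K=4), f_max_hz=0.05)
block = decomp.imf_block("sub-000", 0)          # lowest retained mode
train, val, test, _ = prepare_task(block, 0, WindowSpec(D=24, H=12))

state = fit(train, val,
            GeneratorSpec(m=6, D=24, H=12, gru_hidden=32, fc_nodes=32,
                          cbam_reduction=2, target_index=0),
            config=TrainConfig(supervised_epochs=5, joint_epochs=5,
                               batch_size=32, seed=1))
y_hat = predict(state, test.inputs)
print(rmse(test.targets.ravel(), y_hat.ravel()))                      # 0.0768
print(rmse(test.targets.ravel(),
           persistence_forecast(test.inputs, 0, 12).ravel()))         # 0.1521
```

The trained forecaster's test RMSE (0.0768, normalized scale) is half the
repeat-last-value baseline (0.1521): the network tracks the low-frequency
oscillation into the horizon instead of freezing the last value. The
`examples/` directory holds one short narrative script per capability
(decomposition, forecasting, prolongation, reliability); each prints the
numbers it computes and a line on what they mean.

A thin CLI wraps the same library:

```bash
boldcast simulate --out sim --seed 1
boldcast decompose --input sim/sub-000.csv --tr 0.72 --k 4 --out dec.h5
boldcast run --config config.yaml --out artifacts --seed 1   # full pipeline
```

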