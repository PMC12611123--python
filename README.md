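# ecorestore

Hybrid **Cubist–BiGRU–SA** modelling of ecological-restoration outcomes from
multivariate environmental time series, with a synthetic Qinghai–Tibet-Plateau
(QTP)-style monitoring panel as a fully reproducible test bed.

## Who this is for

Quantitative ecologists and modellers who want to predict vegetation
restoration outcomes (restoration rate, survival) from monthly monitoring
panels — temperature, precipitation, soil moisture, fractional vegetation
cover (FVC), irrigation volume, planting density — and to quantify how much
each driver, especially the manual interventions, contributes.

## The model

Three layers act in sequence on a window of `T = 30` monthly observations of
`D = 6` covariates:

1. **Cubist rule-tree feature extractor.** An M5/Cubist-style regression tree
   partitions the per-step covariate space into regions `R_j` by maximizing
   standard-deviation reduction, and fits a local linear model per region:

   `ŷ_i = β₀⁽ʲ⁾ + Σ_k β_k⁽ʲ⁾ x_ik,  x_i ∈ R_j`

   Each step is encoded as a 16-dimensional structured feature vector
   `F = [rule indicators; local prediction; global prediction]`.

2. **Bidirectional GRU (2 × 64 hidden units, dropout 0.3).** Per step:

   `z_t = σ(W_z x_t + U_z h_{t−1} + b_z)`,
   `r_t = σ(W_r x_t + U_r h_{t−1} + b_r)`,
   `h̃_t = tanh(W_h x_t + U_h (r_t ⊙ h_{t−1}) + b_h)`,
   `h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t`,

   run forward and backward and concatenated: `H_t = [h→_t ; h←_t]`.

3. **Scaled dot-product self-attention + affine head.**
   `A = softmax(QKᵀ/√d_k)` with `Q = HW_Q`, `K = HW_K`, `V = HW_V`; the per-row
   contexts `A·V` are averaged into one vector and mapped to the prediction.
   The column means of `A` are the per-step importances `α_t` ("critical
   moments").

Training follows a strictly chronological protocol (70/20/10 split on window
end dates, rolling-origin CV helpers, early stopping on validation loss,
Adam, lr 0.001, batch 32), entirely in NumPy with a hand-written backward
pass. Interpretation comes from an in-package permutation-sampling Shapley
estimator (mean-|φ| variable ranking) and an irrigation dose–response
analysis over arid (< 200 mm/yr) sites.

## Worked example

```python
from ecorestore import CubistBiGRUSA, ScenarioConfig, TrainConfig, dose_response
from ecorestore.simulate import generate_panel

model = CubistBiGRUSA.from_scenario(ScenarioConfig(seed=42),
                                    TrainConfig(seed=42, max_epochs=30))
res = model.fit("full")
print(res.summary())
```

```
Cubist-BiGRU-SA regression results
==========================================================
variant:        full
task:           restoration_rate
windows:        3217 (train 2252 / val 643 / test 322)
window length:  T=30, D=6 variables
cubist:         14 rules, m=16 features
training:       stopped at epoch 25, best epoch 15
----------------------------------------------------------
split         rmse     mape%        r2      acc%       n
train       0.0129      1.71    0.9976      99.7    2252
val         0.0110      1.62    0.9980     100.0     643
test        0.0144      1.68    0.9973     100.0     322
----------------------------------------------------------
test accuracy by altitude band (+/-10% relative error):
  low    100.0%  (n=96)
  mid    100.0%  (n=161)
  high   100.0%  (n=65)
```

The benchmark panel holds 104 sites × 60 months (2019–2023), windowed into
3,217 samples. `acc%` is the share of samples whose relative prediction error
is within ±10%; on this synthetic benchmark the trained hybrid recovers the
restoration-rate signal essentially to the generator's noise floor in every
altitude band (< 3500 m, 3500–4500 m, > 4500 m). The irrigation
dose–response over a purely arid scenario:

```python
dr = dose_response(generate_panel(ScenarioConfig(n_sites=320, arid_fraction=1.0, seed=123)))
print(f"+{dr.gain_per_10pp:.1f} pp survival per +10 pp irrigation; "
      f"survival at 40% irrigation: {dr.fitted_at[40.0]:.1f}%")
# +15.0 pp survival per +10 pp irrigation; survival at 40% irrigation: 60.0%
```

There is also a CLI (`ecorestore simulate|preprocess|train|evaluate|explain|compare`)
that writes metrics CSVs, model bundles, attribution tables and a JSON run
manifest per command.

## Layout

| Module | Contents |
| --- | --- |
| `ecorestore.simulate` | scenario config, panel generator, missingness injection |
| `ecorestore.preprocess` | interpolation, robust outlier screen, seasonal adjustment, windowing, standardization |
| `ecorestore.cubist` | SDR rule-tree induction, rule features, JSON serialization |
| `ecorestore.bigru` / `attention` | layer mathematics, one sequence at a time |
| `ecorestore.network` | batched forward/backward (BPTT), Adam, training loop |
| `ecorestore.pipeline` | chronological splits, metrics, paired t-test, ablation variants |
| `ecorestore.model` | `CubistBiGRUSA` / `CubistBiGRUSAResults` (fit / summary / plots / save) |
| `ecorestore.attribution` | sampling Shapley values, global importance, dose–response |
| `ecorestore.cli` / `io` | command-line surface, CSV/config/manifest I/O |

See `docs/methods.md` for the modelling assumptions, generator design and
known limitations.
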