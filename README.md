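# stpanel

Spatiotemporal forecasting of regional health-surveillance panels —
disease incidence, hospitalization rates and their covariates observed
over time across connected regions — with attention-based temporal and
cross-feature encoding, graph-convolutional spatial aggregation, and an
adaptive robustness layer for the noisy, anomalous and incomplete data
that surveillance systems actually produce.

## What it computes

The data are a panel `x ∈ R^{T×V×M}` (time × region × feature) with an
observation mask, a region adjacency graph `A`, and an outcome
`y_{t,v}` to forecast from the window `x_{t-L}, …, x_t`.

**Forecaster.** Each feature series in the window is encoded by a gated
recurrent cell

    g_t = σ(W_g y_t + U_g z_{t-1} + b_g),   i_t = σ(W_i y_t + U_i z_{t-1} + b_i)
    z_t = g_t ⊙ z_{t-1} + i_t ⊙ tanh(W_z y_t + U_z z_{t-1} + b_z)

at several temporal resolutions (mean-pooled windows, factors {1,2,4}),
with learned softmax weights mixing the scales. Feature embeddings
exchange information through temperature-scaled dot-product attention
`β^(m,m') = softmax_{m'}(h^(m)·h^(m')/τ)` with residual blending
`h̃ = λh + (1-λ)βh`, and regions exchange information through multi-hop
degree-normalized graph convolution
`s_v = act(Σ_u A_uv/√(D_vv D_uu) W h_u + b)` with learned convex hop
mixing. The prediction is a linear head over the concatenated temporal,
cross-feature and fused spatial representations,
`ŷ = w_p^T[c; g; s] + b_p`. Training minimizes

    L_total = MSE + λ₁‖w_p‖² + λ₂Σ‖W_g‖² + λ₃‖W_h‖² + α·L_temp + L_conf

where `L_temp` penalizes jumps between consecutive forecasts and
`L_conf` discourages persistently dominant features.

**Robustness layer.** Before modelling: (i) each feature is scaled by a
confidence score `γ = exp(-σ_t/(σ̄+ε))` from its rolling dispersion
(optionally EMA-smoothed); (ii) anomaly scores
`δ_t = mean_m |x_t - μ_t|` against a trailing baseline attenuate the
temporal attention, either subtractively (`e - λδ`) or through the
saturating gate `f(δ) = 1 - exp(-κδ)`; (iii) every missing cell is
filled by a convex blend `α·(spatial) + (1-α)·(temporal)` of
degree-normalized observed neighbors and exponentially decayed observed
lags, with `α` adapting to how trustworthy each side is.

Everything is implemented in NumPy over a purpose-built reverse-mode
autodiff engine, at double precision, so analytic gradients are
verifiable against finite differences.

## Worked example

```python
import numpy as np
import stpanel as sp

graph = sp.make_graph("grid", 9, seed=0)
params = sp.SimParams(n_regions=9, n_features=3, T=200, seed=0)
clean, _ = sp.simulate_panel(graph, params)
panel, _ = sp.inject_anomalies(clean, [(60, 2, 4.0), (140, 7, 4.0)])
panel, masked = sp.inject_missing(panel, 0.10, seed=1)

filled, report = sp.impute_missing(panel, graph)
mae = np.mean(np.abs(filled.values[~panel.mask] - clean.values[~panel.mask]))

task = sp.ForecastTask(window=8)
train, val, test = sp.chronological_split(filled, task)
est = sp.PanelForecaster(window=8, learning_rate=5e-3, max_epochs=120,
                         anomaly_attention=True, seed=0)
est.fit(train, graph, validation=val)
metrics = sp.evaluate(est, test)
```

Output:

```
panel: (200, 9, 3) (time x region x feature), 540 missing cells
imputed 540 cells, MAE vs ground truth: 0.943
stopped at epoch 49, best validation MSE 0.758
test MSE 0.852, MAE 0.726
mean-baseline MSE 3.574
```

The imputer reconstructs the 540 hidden cells to within about one
observation-noise-plus-dynamics unit; the trained forecaster reaches a
test MSE of 0.852 on held-out chronological data, about four times
better than predicting the test mean (3.574), and early stopping picks
the checkpoint at the validation minimum.

`PanelForecaster` is an sklearn-style estimator (`fit` / `predict` /
`get_params` / `set_params`), and `AdaptiveImputer` a transformer, so
both compose with sklearn tooling. A `stpanel` console script exposes
`simulate`, `impute`, `train`, `predict`, `evaluate` and `gradcheck`
for file-based workflows (long CSV panels, JSON/TSV graphs, JSON
checkpoints).

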