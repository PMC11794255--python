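# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the tests do and do not establish.

## Problem and data model

The unit of analysis is a regional surveillance panel: `M` indicators
observed at `T` time points in `V` regions connected by a fixed,
symmetric, nonnegative adjacency `A` (geographic contiguity, mobility,
or any other linkage). The forecast target `y_{t,v}` is a per-region
outcome predicted from the `L+1` most recent slices
`x_{t-L}, …, x_t`; with the default horizon of 1 the target is aligned
with the window's final slice, and larger horizons shift it further
ahead. Windowing yields `T - L - horizon + 1` supervised pairs.
Chronological splitting (default 80:10:10, floored, remainder to
train) precedes windowing, so no window spans a split boundary.

Missing cells carry NaN and a False mask bit; no model arithmetic ever
reads them — training and prediction require a fully observed (i.e.
imputed) panel and raise otherwise.

## Forecaster

**Temporal encoding.** Each feature's scalar series is encoded
independently with shared parameters by a two-gate recurrent cell
(forget gate, input gate, tanh candidate; no output gate). This cell is
written out directly rather than borrowed from a standard library
because its gate structure is not an LSTM or GRU. Layers stack by
feeding the full state sequence forward; the initial state is zero;
inverted dropout (default 0.3) is applied to non-final layer outputs
during training only.

**Multi-scale branch.** The raw window is mean-pooled at factors
{1, 2, 4} (non-overlapping blocks aligned to the newest lag; an
incomplete oldest block is dropped; a factor longer than the window is
an error), each pooled window is encoded with the shared cell, and the
per-scale representations are mixed by a softmax over learned scale
scores. Cell and attention parameters are shared across scales for
parameter economy. The "spectral filtering" alternative to mean
pooling is not implemented; mean pooling is the package's downsampler.

**Attention normalization.** The temporal attention template scores
states with `q·tanh(Qz + c)`. As printed, the score normalization runs
over time while the pooled sum runs over features, which would make the
pooled context non-convex. The package normalizes over the axis being
summed — features — so every context vector is a convex combination of
its inputs, and pools the time axis by taking the final-lag state
(default) or by anomaly-aware lag attention (opt-in,
`anomaly_attention=True`). The `axis` argument of
`temporal_attention` exposes the choice rather than hiding it.

**Cross-feature attention.** Scaled dot-product weights with the
temperature learned in log-space (positivity by construction), self
included in the support (an exclusion mask is available), residual
blending with a learnable weight in [0, 1], and a second-order
tanh-scored self-attention. The paper-level operators leave open
whether the refined embeddings replace or summarize `h̃`; here the
refinement pools them into the single vector `g_t` the head consumes,
and the unpooled refined weights are also returned.

**Spatial aggregation.** Symmetric degree normalization
`A_uv/√(D_vv D_uu)`; self-loops are added (and degrees recomputed)
for aggregation, so a region keeps its own signal, but are excluded
from the imputation weights (neighbors only). Hop parameters are
untied; hop mixing uses a softmax over logits so the mixture is convex;
`K = 0` returns the input unchanged. The plain weighted neighbor sum is
the special case `W = I, b = 0`, identity activation, verified by test.

**Fusion and head.** The fused representation is
`λ·X_temporal + (1-λ)·X_spatial` with `λ` a sigmoid-parameterized
learnable weight. The hierarchical refinement attends, per region, over
the candidate set {temporal, spatial, fused} with a learned query —
the "context" of the refinement template is not defined by its source,
so this per-region convex re-weighting is the package's bridge
decision; weights sum to 1 by construction. The head is linear over
the concatenation `[c_t; g_t; s_t]`.

`mode="linear"` bypasses everything and computes
`ŷ = w_p·x_t + b_p` on the window's last slice. This is the
configuration in which the model is provably able to recover the
synthetic generator's outcome weights, and the recovery test uses it.

## Robustness layer

**Confidence scores.** `γ = exp(-σ_t/(σ̄+ε))` with `σ_t` a trailing
rolling standard deviation over `W_σ = 14` steps (population std over
observed entries) and `σ̄` the long-run *mean of the rolling stds* —
a mean of standard deviations, as specified, not the overall std. EMA
mode replaces `σ_t` with `δ_t = α_ema δ_{t-1} + (1-α_ema)σ_t`
(initialized from 0, `α_ema = 0.9`). Warm-up rule: with fewer than two
observed points the neutral value `γ = 1` applies; statistics never
raise at the series start. Scores multiply the per-feature embeddings
(`h̃ = γh`) and feed the balance penalty
`L_conf = λ_reg Σ_m (mean_t γ)²`.

**Anomaly attenuation.** `δ_t = mean_m |x_t - μ_t|` with `μ_t` the
mean of up to `W_μ = 14` observations *strictly before* `t` (a spike
must not launder its own baseline); fewer than two prior points give
`δ = 0`. Scores are per region for regional panels, averaged for a
global series. Two attenuation variants are kept because both are
defined and neither is designated final: subtractive
(`softmax(e - λδ)`) and multiplicative (`softmax(e·(1-f(δ)))` with
`f(δ) = 1 - exp(-κδ)`); multiplicative is the default as the later
refinement. Defaults `λ = κ = 1`.

**Imputation.** Each masked cell is filled once, deterministically,
from originally observed values only (so the result is independent of
fill order):

* spatial side — observed neighbors under the loop-free normalized
  weights, renormalized over the observed neighbors so the estimate is
  level-unbiased regardless of degree;
* temporal side — observed lags `1…L_imp` weighted by
  `exp(-ρτ)` renormalized over the observed lags (`ρ = 0.5`,
  `L_imp = 8` by default; `ρ = 0` gives uniform weights);
* blend — `α` fixed or adaptive. The confidence quantities the blend
  needs are not operationally defined at the paper level; the package
  defines the spatial confidence of neighbor `u` as its renormalized
  weight times its observed fraction over the trailing `W_σ` steps, and
  the temporal confidence of lag `τ` as its decay weight *normalized
  over the full lookback* times the observed indicator — so missing
  history genuinely lowers the temporal side's credibility. Then
  `α = S/(S+H)`.
* fallback chain — no observed neighbors forces `α = 0`; no observed
  history forces `α = 1`; both empty falls back to the feature's global
  observed mean; a feature observed nowhere is a hard error. Every fill
  is recorded in a report (cell, value, α, source counts, fallback).

Every fill is a convex combination of observed values of the same
feature, so imputed values cannot leave the observed range — asserted
as an invariant test. Multiple imputation and uncertainty propagation
are out of scope by design: one deterministic fill per cell.

## Loss

`L_total = MSE + λ₁‖w_p‖² + λ₂Σ_k‖W_g^(k)‖² + λ₃‖W_h‖² + α·L_temp +
L_conf` with `L_temp` the mean squared difference of consecutive
predictions, computed per region and averaged (the per-region-or-pooled
question is resolved this way and tested). A single-step batch disables
`L_temp` with a warning rather than dividing by zero. Default
coefficients, chosen once as mild regularization in the absence of
stated values: `λ₁ = λ₂ = λ₃ = 1e-4`, `α = 0.5`, `λ_reg = 1e-3`; all
are config fields.

## Training protocol

AdamW (decoupled weight decay, default decay 0 because the ridge terms
already live in the loss), learning rate default `1e-5` with an
optional cosine schedule, batch size 32, dropout 0.3, global
gradient-norm clipping at 1.0 before every step (post-clip norms are
recorded per epoch and asserted ≤ 1 in tests), early stopping on
validation MSE with patience 20 (fixed epoch counts in the protocol's
source are dataset-specific and do not transfer to synthetic panels),
and three-seed repetition with mean ± sd reporting. Every random
draw — initialization, batching, dropout — comes from one seeded
generator, so retraining with the same seed reproduces the loss trace
bit-for-bit; this is asserted by test.

All computation is float64. The `precision="single"` option only
rounds the stored parameters to float32; the gradient checker refuses
it, since central differences at step `1e-6` are meaningless in single
precision.

## Numerical engine

No autodiff framework is available in the dependency set, so the
package carries a small reverse-mode engine (`stpanel.autodiff`):
a tape of NumPy array operations (broadcast arithmetic, batched matmul,
reductions, indexing, concatenation, the usual nonlinearities) with an
iterative topological backward pass. Softmax subtracts a detached
running maximum — exact for gradients because softmax is
shift-invariant. The engine's primitives and the full composite loss
are verified against central finite differences (relative error below
`1e-4` for the full model; near machine precision for the quadratic
linear-mode objective).

## Synthetic generator

A linear-Gaussian state-space panel: per-region latent states follow
`s_t = a·s_{t-1} + c·W s_{t-1} + ε_state` (AR coefficient `a = 0.6`,
spatial diffusion `c = 0.2` through the normalized graph weights;
stationarity — spectral radius of `aI + cW` below 1 — is enforced),
features load linearly on the latents with observation noise
(sd 0.25 against unit state noise), and the outcome is a linear map of
the features plus noise (sd 0.1). These defaults describe a moderately
autocorrelated, weakly diffusing panel — the regime regional
surveillance indicators typically occupy — and the linear-Gaussian core
is deliberate: it makes the linearized forecaster's weight-recovery
test well-posed. Missingness is MCAR or temporal-block; anomalies are
additive level shifts across all features of a (time, region) event.

What the generator does *not* emulate: mechanistic epidemic dynamics
(SIR-type nonlinearity), seasonality, reporting delays, count-valued
observations, or informative missingness. Passing tests therefore
establish correctness of the implementation and recoverability under
the stated statistical structure, not performance on real surveillance
data.

## Problem sizes used in the acceptance runs

Chosen once as the smallest sizes at which each property is
well-measured: the forecasting pipeline uses a 9-region grid, 3
features, T = 200, 10% MCAR missingness and four injected anomalies;
weight recovery uses 4 regions, 1 feature, T = 500, outcome noise 0.1,
three seeds; overfit capacity uses 50 windows of a noiseless 4-region
panel; the gradient check uses 2 regions, 2 features, L = 3. Training
runs in these scripts use learning rates around `5e-3`–`5e-2` — the
protocol's `1e-5` default is tuned to fine-tuning regimes far larger
than these panels and is kept as the package default, not as the
script setting.

## Known limitations

* The forward pass is a NumPy interpretation loop; it is fast enough
  for panels of tens of regions and hundreds of time steps, not for
  thousands.
* Adjacency is fixed; no learned or time-varying graphs.
* The classification metrics sometimes reported alongside this family
  of models do not apply: the artifact is a regression method, and no
  classification head is provided.
* Single deterministic imputation; downstream variance is understated
  when missingness is heavy.
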