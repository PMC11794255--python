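"""The spatiotemporal panel forecaster.

`PanelForecaster` is an sklearn-style regressor over
:class:`~stpanel.panel.PanelDataset` inputs. Its forward pass wires the
component modules together, per history window and region:

1. multi-scale temporal branch — the raw window is mean-pooled at each
   down-sampling factor, encoded by the shared gated recurrent cell per
   feature, attention-pooled over features, and the per-scale vectors
   mixed by learned softmax weights → temporal context ``c_t``;
2. cross-feature branch — per-feature states at the native scale
   (final-lag, or anomaly-aware lag attention when enabled) are scaled
   by confidence scores, exchanged through temperature-scaled
   cross-feature attention with residual blending, and pooled by a
   second-order self-attention → cross-feature vector ``g_t``;
3. spatial branch — the temporal context is aggregated over the region
   graph by multi-hop degree-normalized convolution, blended with the
   temporal context through a learnable convex weight, and refined by a
   per-region hierarchical attention over the candidate set
   {temporal, spatial, fused} → spatial vector ``s_t``;
4. head — ``y_hat = w_p . [c_t; g_t; s_t] + b_p``.

``mode="linear"`` bypasses the encoder and attention entirely:
``y_hat = w_p . x_t + b_p`` on the window's last slice — the
configuration under which the model provably recovers the generative
outcome weights of :mod:`stpanel.simulate`.

Training uses AdamW with an optional cosine schedule, global gradient
clipping, dropout in the encoder stack, and early stopping on a
validation panel; everything is reproducible from the ``seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .autodiff import Tensor, softmax, stack
from . import adjust, crossfeat, fusion, spatial, temporal
from .fusion import LossConfig
from .optim import AdamW, clip_gradients, cosine_lr
from .panel import ForecastTask, PanelDataset, RegionGraph, make_windows

__all__ = ["PanelForecaster"]

CHECKPOINT_VERSION = 1


class PanelForecaster(RegressorMixin, BaseEstimator):
    """Graph-attentive forecaster for regional surveillance panels.

    Parameters
    ----------
    window, horizon : int
        History length L (the window spans L+1 slices) and forecast
        horizon (1 = outcome aligned with the window's last slice).
    hidden_dim, attn_dim, n_layers : int
        Encoder state size, attention projection size, encoder depth.
    scale_set : tuple of int
        Down-sampling factors of the multi-scale branch.
    n_hops : int
        Graph-aggregation hops K (0 disables spatial mixing).
    activation : {"relu", "sigmoid", "tanh", "identity"}
    mode : {"full", "linear"}
        "linear" reduces the model to y = w_p . x_t + b_p.
    confidence_weighting : bool
        Scale per-feature embeddings by their reliability score.
    confidence_mode : {"window", "ema"}
    anomaly_attention : bool
        Pool window lags by anomaly-attenuated attention instead of
        taking the final-lag state.
    attention_variant : {"multiplicative", "subtractive"}
    lambda_anom, kappa : float
        Anomaly-attention sensitivity and gate saturation rate.
    W_sigma, W_mu, alpha_ema, epsilon :
        Rolling-statistic settings of the confidence/anomaly scores.
    tau_init, lambda_blend_init, lambda_fuse_init : float
        Initial temperature and blend weights (all learnable).
    lambda1, lambda2, lambda3, alpha_temp, lambda_reg : float
        Loss coefficients (see :class:`~stpanel.fusion.LossConfig`).
    learning_rate, batch_size, max_epochs, patience, clip_norm,
    dropout, cosine_schedule, weight_decay :
        Optimization settings. ``patience`` counts epochs without
        validation improvement before stopping (ignored without a
        validation panel).
    seed : int
        Drives parameter initialization, batching and dropout.

    Attributes
    ----------
    params_ : dict of str -> Tensor
        Fitted parameter arrays.
    report_ : pandas.DataFrame
        Per-epoch loss components, validation trace, learning rate and
        post-clipping gradient norms.
    best_epoch_, n_features_in_, regions_, graph_ : fitted metadata.
    """

    def __init__(self, window: int = 8, horizon: int = 1, hidden_dim: int = 8,
                 attn_dim: int = 8, n_layers: int = 1,
                 scale_set: tuple = (1, 2, 4), n_hops: int = 2,
                 activation: str = "relu", mode: str = "full",
                 confidence_weighting: bool = True,
                 confidence_mode: str = "window",
                 anomaly_attention: bool = False,
                 attention_variant: str = "multiplicative",
                 lambda_anom: float = 1.0, kappa: float = 1.0,
                 W_sigma: int = 14, W_mu: int = 14, alpha_ema: float = 0.9,
                 epsilon: float = 1e-8, tau_init: float = 1.0,
                 lambda_blend_init: float = 0.5, lambda_fuse_init: float = 0.5,
                 lambda1: float = 1e-4, lambda2: float = 1e-4,
                 lambda3: float = 1e-4, alpha_temp: float = 0.5,
                 lambda_reg: float = 1e-3, learning_rate: float = 1e-5,
                 batch_size: int = 32, max_epochs: int = 200,
                 patience: int = 20, clip_norm: float = 1.0,
                 dropout: float = 0.3, cosine_schedule: bool = True,
                 weight_decay: float = 0.0, init_scale: float = 0.2,
                 seed: int = 0):
        self.window = window
        self.horizon = horizon
        self.hidden_dim = hidden_dim
        self.attn_dim = attn_dim
        self.n_layers = n_layers
        self.scale_set = scale_set
        self.n_hops = n_hops
        self.activation = activation
        self.mode = mode
        self.confidence_weighting = confidence_weighting
        self.confidence_mode = confidence_mode
        self.anomaly_attention = anomaly_attention
        self.attention_variant = attention_variant
        self.lambda_anom = lambda_anom
        self.kappa = kappa
        self.W_sigma = W_sigma
        self.W_mu = W_mu
        self.alpha_ema = alpha_ema
        self.epsilon = epsilon
        self.tau_init = tau_init
        self.lambda_blend_init = lambda_blend_init
        self.lambda_fuse_init = lambda_fuse_init
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.alpha_temp = alpha_temp
        self.lambda_reg = lambda_reg
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.clip_norm = clip_norm
        self.dropout = dropout
        self.cosine_schedule = cosine_schedule
        self.weight_decay = weight_decay
        self.init_scale = init_scale
        self.seed = seed

    # -- construction ----------------------------------------------------

    def _task(self) -> ForecastTask:
        return ForecastTask(window=self.window, horizon=self.horizon)

    def _loss_config(self) -> LossConfig:
        return LossConfig(self.lambda1, self.lambda2, self.lambda3,
                          self.alpha_temp, self.lambda_reg)

    def build_params(self, n_features: int,
                     rng: np.random.Generator) -> dict[str, Tensor]:
        """Initialize every learnable array for a panel with M features."""
        if self.mode == "linear":
            return {
                "head.w_p": Tensor(rng.normal(0, self.init_scale, n_features),
                                   requires_grad=True),
                "head.b_p": Tensor(0.0, requires_grad=True),
            }
        d, a, s = self.hidden_dim, self.attn_dim, self.init_scale
        p: dict[str, Tensor] = {}
        for layer in range(self.n_layers):
            in_dim = 1 if layer == 0 else d
            p.update(temporal.init_gated_cell(in_dim, d, rng, s,
                                              prefix=f"cell{layer}"))
        p.update(temporal.init_attention(d, a, rng, s, prefix="featattn"))
        if self.anomaly_attention:
            p.update(temporal.init_attention(d, a, rng, s, prefix="lagattn"))
        p.update(crossfeat.init_cross_feature(
            d, a, rng, s, self.tau_init, self.lambda_blend_init, prefix="xf"))
        p.update(spatial.init_gcn(d, self.n_hops, rng, s, prefix="gcn"))
        p["fusion.scale_scores"] = Tensor(np.zeros(len(self.scale_set)),
                                          requires_grad=True)
        lam = float(np.clip(self.lambda_fuse_init, 1e-6, 1 - 1e-6))
        p["fusion.fuse_logit"] = Tensor(np.log(lam / (1 - lam)),
                                        requires_grad=True)
        p.update(fusion.init_fuse(d, a, rng, s, prefix="fuse"))
        p["head.w_p"] = Tensor(rng.normal(0, s, 3 * d), requires_grad=True)
        p["head.b_p"] = Tensor(0.0, requires_grad=True)
        return p

    def ridge_groups(self, params: dict[str, Tensor]) -> dict:
        groups = {"w_p": params["head.w_p"]}
        W_g = [params[k] for k in sorted(params)
               if k.startswith("gcn.W")]
        if W_g:
            groups["W_g"] = W_g
        if "xf.W_h" in params:
            groups["W_h"] = params["xf.W_h"]
        return groups

    # -- panel-derived constants ----------------------------------------

    def panel_constants(self, panel: PanelDataset):
        """Confidence scores (T, V, M) and anomaly scores (T, V)."""
        gamma = None
        if self.confidence_weighting and self.mode != "linear":
            gamma = adjust.confidence_scores(
                panel, mode=self.confidence_mode, W_sigma=self.W_sigma,
                alpha_ema=self.alpha_ema, epsilon=self.epsilon)
        delta = None
        if self.anomaly_attention and self.mode != "linear":
            delta = adjust.anomaly_scores(panel, W_mu=self.W_mu)
        return gamma, delta

    # -- forward ---------------------------------------------------------

    def _encode_pooled(self, pooled: np.ndarray, params, train, rng):
        """Pooled window (B, n_lags, V, M) -> feature-pooled context (B, V, d)."""
        states = temporal.encode_sequence(
            pooled[..., None], params, n_layers=self.n_layers, prefix="cell",
            lag_axis=1, dropout=self.dropout, rng=rng, train=train)
        final = states[:, -1]                      # (B, V, M, d)
        _, context = temporal.temporal_attention(final, params,
                                                 prefix="featattn")
        return context

    def forward(self, histories: np.ndarray, params: dict[str, Tensor],
                norm_weights: np.ndarray | None = None, gamma=None,
                deltas=None, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Predictions (B, V) for a stack of history windows (B, L+1, V, M).

        ``gamma`` (B, V, M) and ``deltas`` (B, L+1, V) are the
        window-aligned confidence and anomaly constants.
        """
        if self.mode == "linear":
            x_t = histories[:, -1]                 # (B, V, M)
            return fusion.predict_head(Tensor(x_t), None, None,
                                       params["head.w_p"], params["head.b_p"])

        # temporal branch over scales
        x_temporal, _ = fusion.multiscale_temporal(
            histories, self.scale_set, params["fusion.scale_scores"],
            lambda w: self._encode_pooled(w, params, train, rng), lag_axis=1)

        # cross-feature branch at the native scale
        states = temporal.encode_sequence(
            histories[..., None], params, n_layers=self.n_layers,
            prefix="cell", lag_axis=1, dropout=self.dropout, rng=rng,
            train=train)                           # (B, L+1, V, M, d)
        if self.anomaly_attention and deltas is not None:
            e = ((states @ params["lagattn.Q"] + params["lagattn.c"]).tanh()
                 @ params["lagattn.q"])            # (B, L+1, V, M, 1)
            d_b = deltas[..., None, None]          # (B, L+1, V, 1, 1)
            if self.attention_variant == "subtractive":
                logits = e - Tensor(self.lambda_anom * d_b)
            else:
                gate = adjust.anomaly_gate(d_b, self.kappa)
                logits = e * Tensor(1.0 - gate)
            w_lag = softmax(logits, axis=1)
            h_feat = (w_lag * states).sum(axis=1)  # (B, V, M, d)
        else:
            h_feat = states[:, -1]
        if gamma is not None:
            h_feat = Tensor(gamma[..., None]) * h_feat

        tau = params["xf.log_tau"].exp()
        beta = crossfeat.cross_attention_weights(h_feat, tau)
        lam_blend = params["xf.blend_logit"].sigmoid()
        blended = crossfeat.cross_context_blend(h_feat, beta, lam_blend)
        _, g_t = crossfeat.refine_self_attention(blended, params, prefix="xf")

        # spatial branch + fusion
        if self.n_hops > 0 and norm_weights is not None:
            x_spatial, _ = spatial.multi_hop_aggregate(
                x_temporal, norm_weights, params, self.n_hops,
                self.activation, prefix="gcn")
        else:
            x_spatial = x_temporal
        lam_fuse = params["fusion.fuse_logit"].sigmoid()
        x_fused = fusion.adaptive_fusion(x_temporal, x_spatial, lam_fuse)
        cand = stack([x_temporal, x_spatial, x_fused], axis=-2)
        _, s_t = fusion.hierarchical_refine(cand, params, prefix="fuse")

        return fusion.predict_head(x_temporal, g_t, s_t,
                                   params["head.w_p"], params["head.b_p"])

    # -- fitting ----------------------------------------------------------

    def _prepare(self, panel: PanelDataset, graph: RegionGraph | None):
        if not panel.fully_observed():
            raise ValueError("panel has unobserved cells: impute first "
                             "(stpanel.adjust.impute_missing)")
        if graph is not None and graph.region_ids != panel.region_ids:
            graph = graph.reorder(panel.region_ids)
        norm = spatial.normalize_adjacency(graph, self_loops=True) \
            if graph is not None else None
        hist, targ, t_idx = make_windows(panel, self._task())
        gamma, delta = self.panel_constants(panel)
        gam_w = gamma[t_idx] if gamma is not None else None
        del_w = None
        if delta is not None:
            L = self.window
            starts = t_idx - (L + self.horizon - 1)
            del_w = np.stack([delta[s:s + L + 1] for s in starts])
        return hist, targ, t_idx, gam_w, del_w, gamma, norm, graph

    def fit(self, panel: PanelDataset, graph: RegionGraph | None = None,
            validation: PanelDataset | None = None):
        """Train on a fully observed panel; early-stop on ``validation``."""
        hist, targ, _, gam_w, del_w, gamma, norm, graph = \
            self._prepare(panel, graph)
        rng = np.random.default_rng(self.seed)
        params = self.build_params(panel.shape[2], rng)
        cfg = self._loss_config()
        opt = AdamW(params, lr=self.learning_rate,
                    weight_decay=self.weight_decay)

        val = None
        if validation is not None:
            vh, vt, vti = make_windows(validation, self._task())
            vg, vd = self.panel_constants(validation)
            vgam = vg[vti] if vg is not None else None
            vdel = None
            if vd is not None:
                starts = vti - (self.window + self.horizon - 1)
                vdel = np.stack([vd[s:s + self.window + 1] for s in starts])
            val = (vh, vt, vgam, vdel)

        n = hist.shape[0]
        rows = []
        best_val, best_epoch, best_state, stale = np.inf, 0, None, 0
        for epoch in range(self.max_epochs):
            lr = cosine_lr(self.learning_rate, epoch, self.max_epochs) \
                if self.cosine_schedule else self.learning_rate
            order = rng.permutation(n)
            comp_sum = {"mse": 0.0, "ridge": 0.0, "temp": 0.0,
                        "reg": 0.0, "total": 0.0}
            max_post = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = np.sort(order[start:start + self.batch_size])
                loss, comps = self._batch_loss(
                    hist[idx], targ[idx], params, norm,
                    None if gam_w is None else gam_w[idx],
                    None if del_w is None else del_w[idx],
                    gamma, cfg, train=True, rng=rng)
                if not np.isfinite(comps["total"]):
                    bad = {k: v for k, v in comps.items() if not np.isfinite(v)}
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {bad}")
                opt.zero_grad()
                loss.backward()
                _, post = clip_gradients(params, self.clip_norm)
                max_post = max(max_post, post)
                opt.step(lr=lr)
                for k in comp_sum:
                    comp_sum[k] += comps[k]
                n_batches += 1
            row = {k: v / n_batches for k, v in comp_sum.items()}
            row.update(epoch=epoch, lr=lr, grad_norm_postclip=max_post)

            if val is not None:
                vh, vt, vgam, vdel = val
                vy = self.forward(vh, params, norm, vgam, vdel).data
                row["val_mse"] = float(np.mean((vy - vt) ** 2))
                if row["val_mse"] < best_val - 1e-12:
                    best_val, best_epoch, stale = row["val_mse"], epoch, 0
                    best_state = {k: p.data.copy() for k, p in params.items()}
                else:
                    stale += 1
            rows.append(row)
            if val is not None and stale > self.patience:
                break
        if best_state is not None:
            for k, p in params.items():
                p.data = best_state[k]

        self.params_ = params
        self.norm_weights_ = norm
        self.graph_ = graph
        self.gamma_ = gamma
        self.n_features_in_ = panel.shape[2]
        self.regions_ = list(panel.region_ids)
        self.feature_names_ = list(panel.feature_names)
        self.report_ = pd.DataFrame(rows)
        self.best_epoch_ = best_epoch if val is not None else len(rows) - 1
        return self

    def _batch_loss(self, hist, targ, params, norm, gam_w, del_w, gamma,
                    cfg, train, rng):
        y_hat = self.forward(hist, params, norm, gam_w, del_w,
                             train=train, rng=rng)
        return fusion.total_loss(
            y_hat, targ, cfg, ridge_groups=self.ridge_groups(params),
            gamma=gamma, time_axis=0)

    def loss_on(self, panel: PanelDataset, graph: RegionGraph | None = None,
                params: dict[str, Tensor] | None = None):
        """Composite loss on a panel (no training); for diagnostics/checks."""
        hist, targ, _, gam_w, del_w, gamma, norm, _ = \
            self._prepare(panel, graph if graph is not None else
                          getattr(self, "graph_", None))
        params = params if params is not None else self.params_
        return self._batch_loss(hist, targ, params, norm, gam_w, del_w,
                                gamma, self._loss_config(), False, None)

    # -- inference ---------------------------------------------------------

    def predict(self, panel: PanelDataset, return_times: bool = False):
        """Forecasts, shape (n_windows, V), aligned to the target times."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fit the model (or load a checkpoint) first")
        if not panel.fully_observed():
            raise ValueError("panel has unobserved cells: impute first")
        work = panel
        if work.targets is None:
            work = work.copy()
            work.targets = np.zeros(work.shape[:2])
        hist, _, t_idx, gam_w, del_w, _, norm, _ = \
            self._prepare(work, getattr(self, "graph_", None))
        y = self.forward(hist, self.params_, norm, gam_w, del_w).data
        return (y, t_idx) if return_times else y

    # -- persistence -------------------------------------------------------

    def to_checkpoint(self, path) -> None:
        """Write fitted parameters + config as a versioned JSON container."""
        obj = {
            "format_version": CHECKPOINT_VERSION,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "n_features_in": self.n_features_in_,
            "regions": self.regions_,
            "feature_names": self.feature_names_,
            "params": {k: p.data.tolist() for k, p in self.params_.items()},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_checkpoint(cls, path, graph: RegionGraph | None = None):
        obj = json.loads(Path(path).read_text())
        if obj.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        config = dict(obj["config"])
        if isinstance(config.get("scale_set"), list):
            config["scale_set"] = tuple(config["scale_set"])
        est = cls(**config)
        est.params_ = {k: Tensor(np.asarray(v), requires_grad=True)
                       for k, v in obj["params"].items()}
        est.n_features_in_ = obj["n_features_in"]
        est.regions_ = obj["regions"]
        est.feature_names_ = obj["feature_names"]
        est.graph_ = graph
        est.norm_weights_ = spatial.normalize_adjacency(graph, True) \
            if graph is not None else None
        return est
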