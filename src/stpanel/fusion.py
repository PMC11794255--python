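"""Multi-scale temporal fusion, adaptive temporal/spatial blending,
the prediction head, and the composite training objective.

Multi-scale branch: the raw window is mean-pooled at each down-sampling
factor (non-overlapping blocks aligned to the most recent lag, an
oldest-remainder truncated), each pooled window is encoded, and the
per-scale representations are mixed by softmax weights over learned
scale scores. The temporal mixture is blended with the graph-aggregated
spatial representation through a learnable convex weight, and a final
tanh-scored attention refines the blend per region over the candidate
set {temporal, spatial, fused}.

The objective is
    L_total = MSE + l1 ||w_p||^2 + l2 sum_k ||W_g^(k)||^2 + l3 ||W_h||^2
              + alpha * L_temp + L_conf
with L_temp the mean squared difference of consecutive predictions
(per region, then averaged) and L_conf the confidence-balance penalty
from :func:`stpanel.adjust.feature_regularization`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, softmax
from .adjust import feature_regularization

__all__ = ["LossConfig", "pool_window", "multiscale_temporal",
           "adaptive_fusion", "hierarchical_refine", "predict_head",
           "total_loss"]


@dataclass
class LossConfig:
    """Coefficients of the composite objective (all >= 0).

    lambda1/2/3 : ridge strengths on the head weights w_p, the graph
        aggregation weights W_g^(k), and the cross-feature refinement
        weights W_h. alpha_temp : temporal-consistency strength.
    lambda_reg : confidence-balance strength.
    """

    lambda1: float = 1e-4
    lambda2: float = 1e-4
    lambda3: float = 1e-4
    alpha_temp: float = 0.5
    lambda_reg: float = 1e-3

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "alpha_temp", "lambda_reg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def pool_window(window: np.ndarray, factor: int, lag_axis: int = 1) -> np.ndarray:
    """Non-overlapping mean pooling of the lag axis by ``factor``.

    Blocks are aligned so the newest lag closes the last block; an
    incomplete remainder at the oldest end is dropped. Raises if the
    factor exceeds the window length.
    """
    w = np.asarray(window, dtype=float)
    n = w.shape[lag_axis]
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > n:
        raise ValueError(f"pooling factor {factor} exceeds window length {n}")
    if factor == 1:
        return w
    keep = (n // factor) * factor
    w = np.take(w, np.arange(n - keep, n), axis=lag_axis)
    shape = list(w.shape)
    shape[lag_axis:lag_axis + 1] = [keep // factor, factor]
    return w.reshape(shape).mean(axis=lag_axis + 1)


def multiscale_temporal(window: np.ndarray, scale_set, scale_scores,
                        encode_fn, lag_axis: int = 1):
    """Encode the window at several resolutions and mix the results.

    ``encode_fn`` maps a pooled window (same layout, shorter lag axis)
    to a representation Tensor of fixed shape; ``scale_scores`` is a
    Tensor of per-scale logits. Returns ``(X_temporal, scale_weights)``.
    """
    scale_set = tuple(scale_set)
    if len(scale_set) == 0:
        raise ValueError("scale_set must be non-empty")
    reps = [encode_fn(pool_window(window, s, lag_axis)) for s in scale_set]
    alpha = softmax(as_tensor(scale_scores), axis=-1)
    if alpha.shape[-1] != len(scale_set):
        raise ValueError("one scale score per scale required")
    mixed = reps[0] * alpha[0]
    for i in range(1, len(reps)):
        mixed = mixed + reps[i] * alpha[i]
    return mixed, alpha


def adaptive_fusion(x_temporal, x_spatial, lambda_fuse):
    """X_fused = lambda X_temporal + (1 - lambda) X_spatial."""
    lam = as_tensor(lambda_fuse)
    return lam * as_tensor(x_temporal) + (1.0 - lam) * as_tensor(x_spatial)


def hierarchical_refine(candidates, params, prefix: str = "fuse"):
    """Attention-pool a stack of candidate representations.

    ``candidates`` is (..., n, d) — e.g. the per-region stack
    {temporal, spatial, fused}. Scores q . tanh(W x + b) are softmaxed
    over the candidate axis; returns ``(weights (..., n), pooled)``.
    """
    x = as_tensor(candidates)
    scores = (x @ params[f"{prefix}.W"] + params[f"{prefix}.b"]).tanh() \
        @ params[f"{prefix}.q"]
    weights = softmax(scores, axis=-2)
    pooled = (weights * x).sum(axis=-2)
    w = weights[tuple([slice(None)] * (weights.ndim - 1) + [0])]
    return w, pooled


def init_fuse(dim: int, attn_dim: int, rng: np.random.Generator,
              scale: float = 0.2, prefix: str = "fuse"):
    return {
        f"{prefix}.W": Tensor(rng.normal(0, scale, (dim, attn_dim)),
                              requires_grad=True),
        f"{prefix}.b": Tensor(np.zeros(attn_dim), requires_grad=True),
        f"{prefix}.q": Tensor(rng.normal(0, scale, (attn_dim, 1)),
                              requires_grad=True),
    }


def predict_head(c, g, s, w_p, b_p) -> Tensor:
    """y_hat = w_p . [c; g; s] + b_p over the trailing axis.

    Any of c/g/s may be None (the linearized configuration drops
    branches); w_p must match the concatenated dimension.
    """
    parts = [as_tensor(x) for x in (c, g, s) if x is not None]
    if not parts:
        raise ValueError("at least one representation required")
    x = parts[0] if len(parts) == 1 else concatenate(parts, axis=-1)
    w = as_tensor(w_p)
    out = x @ w.reshape(w.shape[0], 1) + as_tensor(b_p)
    return out[tuple([slice(None)] * (out.ndim - 1) + [0])]


def total_loss(y_hat, y, cfg: LossConfig, ridge_groups=None, gamma=None,
               time_axis: int = 0):
    """Composite objective; returns ``(scalar Tensor, component dict)``.

    ``ridge_groups`` is a dict with optional keys "w_p", "W_g" (list of
    Tensors), "W_h". ``y_hat`` is ordered along ``time_axis``; the
    temporal-consistency term uses consecutive differences along it and
    is skipped (with a warning) when fewer than two steps exist.
    ``gamma`` is the confidence-score array for the balance penalty.
    """
    y_hat = as_tensor(y_hat)
    y = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=float)
    mse = ((y_hat - Tensor(y)) ** 2).mean()

    ridge = Tensor(0.0)
    groups = ridge_groups or {}
    if cfg.lambda1 and "w_p" in groups:
        ridge = ridge + cfg.lambda1 * (groups["w_p"] ** 2).sum()
    if cfg.lambda2 and "W_g" in groups:
        for W in groups["W_g"]:
            ridge = ridge + cfg.lambda2 * (W ** 2).sum()
    if cfg.lambda3 and "W_h" in groups:
        ridge = ridge + cfg.lambda3 * (groups["W_h"] ** 2).sum()

    T = y_hat.shape[time_axis] if y_hat.ndim else 1
    if T >= 2:
        sl_hi = tuple(slice(1, None) if a == time_axis else slice(None)
                      for a in range(y_hat.ndim))
        sl_lo = tuple(slice(None, -1) if a == time_axis else slice(None)
                      for a in range(y_hat.ndim))
        temp = ((y_hat[sl_hi] - y_hat[sl_lo]) ** 2).mean()
    else:
        warnings.warn("fewer than two time steps: temporal-consistency "
                      "term disabled", stacklevel=2)
        temp = Tensor(0.0)

    reg = feature_regularization(gamma, cfg.lambda_reg) if gamma is not None else 0.0
    total = mse + ridge + cfg.alpha_temp * temp + reg
    components = {
        "mse": float(mse.data), "ridge": float(ridge.data),
        "temp": float(temp.data), "reg": float(reg), "total": float(total.data),
    }
    return total, components
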