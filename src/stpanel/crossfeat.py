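"""Temperature-scaled attention among feature embeddings.

Features influence one another (e.g. mobility driving case counts), so
each feature embedding attends to all features via scaled dot products:

    beta(m, m') = softmax_{m'} ( h^(m) . h^(m') / tau )

with temperature tau > 0 controlling sharpness. The attended context is
blended back residually, h~ = lambda h + (1 - lambda) (beta h), and a
second tanh-scored self-attention pools the enhanced embeddings into a
single cross-feature vector for the prediction head.

tau is learned in log-space (guaranteeing positivity) and the blend
weight through a sigmoid of a logit (guaranteeing [0, 1]).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, softmax

__all__ = ["init_cross_feature", "cross_attention_weights",
           "cross_context_blend", "refine_self_attention"]


def init_cross_feature(dim: int, attn_dim: int, rng: np.random.Generator,
                       scale: float = 0.2, tau: float = 1.0,
                       lambda_blend: float = 0.5, prefix: str = "xf"):
    """Parameters: refinement scorer (W_h, b_h, w), log tau, blend logit."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    lam = np.clip(lambda_blend, 1e-6, 1 - 1e-6)
    return {
        f"{prefix}.W_h": Tensor(rng.normal(0, scale, (dim, attn_dim)),
                                requires_grad=True),
        f"{prefix}.b_h": Tensor(np.zeros(attn_dim), requires_grad=True),
        f"{prefix}.w": Tensor(rng.normal(0, scale, (attn_dim, 1)),
                              requires_grad=True),
        f"{prefix}.log_tau": Tensor(np.log(tau), requires_grad=True),
        f"{prefix}.blend_logit": Tensor(np.log(lam / (1 - lam)),
                                        requires_grad=True),
    }


def cross_attention_weights(embeddings, tau=1.0, exclude_self: bool = False):
    """Row-stochastic influence matrix beta (..., M, M) over features.

    ``embeddings`` is (..., M, d); ``tau`` a positive scalar (float or
    Tensor). Self-similarity is in the softmax support by default; with
    ``exclude_self`` the diagonal is masked out.
    """
    h = as_tensor(embeddings)
    if not isinstance(tau, Tensor) and tau <= 0:
        raise ValueError("tau must be > 0")
    sim = (h @ h.swapaxes(-1, -2)) / tau
    if exclude_self:
        M = h.shape[-2]
        if M < 2:
            raise ValueError("cannot exclude self with a single feature")
        sim = sim + Tensor(np.where(np.eye(M, dtype=bool), -1e30, 0.0))
    return softmax(sim, axis=-1)


def cross_context_blend(embeddings, weights, lambda_blend):
    """h~ = lambda h + (1 - lambda) g with g(m) = sum_m' beta(m,m') h(m')."""
    h, beta = as_tensor(embeddings), as_tensor(weights)
    g = beta @ h
    lam = as_tensor(lambda_blend)
    return lam * h + (1.0 - lam) * g


def refine_self_attention(enhanced, params, prefix: str = "xf"):
    """Second-order pooling of enhanced embeddings into one vector.

    Scores w . tanh(W_h h~ + b_h) per feature, softmaxed over features;
    returns ``(weights (..., M), pooled (..., d))`` where pooled is the
    convex combination sum_m alpha(m) h~(m).
    """
    h = as_tensor(enhanced)
    scores = (h @ params[f"{prefix}.W_h"] + params[f"{prefix}.b_h"]).tanh() \
        @ params[f"{prefix}.w"]
    weights = softmax(scores, axis=-2)
    pooled = (weights * h).sum(axis=-2)
    w = weights[tuple([slice(None)] * (weights.ndim - 1) + [0])]
    return w, pooled
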