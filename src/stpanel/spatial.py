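"""Degree-normalized graph aggregation across regions with multi-hop
recursion and learned hop mixing.

One aggregation round maps region embeddings h through

    s_v = act( sum_{u in N(v)} A_uv / sqrt(D_vv D_uu) W h_u + b )

— a graph-convolution layer over the fixed region adjacency. Hops are
recursed with untied per-hop parameters, s^(0) = h, and mixed by a
softmax-parameterized convex combination sum_k alpha^(k) s^(k), so
local and distant spatial context are balanced by learned weights.

Self-loops are added (and degrees recomputed) by default for
aggregation, so a region retains its own signal; the imputation weights
in :mod:`stpanel.adjust` use the loop-free normalization (neighbors
only).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, softmax
from .panel import RegionGraph

__all__ = ["normalize_adjacency", "init_gcn", "gcn_layer",
           "multi_hop_aggregate", "ACTIVATIONS"]

ACTIVATIONS = {
    "relu": lambda x: x.relu(),
    "sigmoid": lambda x: x.sigmoid(),
    "tanh": lambda x: x.tanh(),
    "identity": lambda x: x,
}


def normalize_adjacency(graph: RegionGraph, self_loops: bool = False) -> np.ndarray:
    """Symmetric normalization w_uv = A_uv / sqrt(D_vv D_uu).

    With ``self_loops`` the identity is added to A and degrees are
    recomputed before normalizing.
    """
    A = graph.adjacency.copy()
    if self_loops:
        A = A + np.eye(A.shape[0])
    d = A.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
    return A * np.outer(inv, inv)


def init_gcn(dim: int, n_hops: int, rng: np.random.Generator,
             scale: float = 0.2, prefix: str = "gcn"):
    """Untied per-hop weights/biases plus hop-mixture logits (K+1 of them)."""
    if n_hops < 0:
        raise ValueError("n_hops must be >= 0")
    p = {f"{prefix}.hop_logits": Tensor(np.zeros(n_hops + 1), requires_grad=True)}
    for k in range(1, n_hops + 1):
        p[f"{prefix}.W{k}"] = Tensor(rng.normal(0, scale, (dim, dim)),
                                     requires_grad=True)
        p[f"{prefix}.b{k}"] = Tensor(np.zeros(dim), requires_grad=True)
    return p


def gcn_layer(node_features, norm_weights, W, b, activation: str = "relu"):
    """One aggregation round: act(w_norm (h W) + b).

    ``node_features`` is (..., V, d_in); ``norm_weights`` a constant
    (V, V) matrix; ``W`` (d_in, d_out), ``b`` (d_out,).
    """
    h = as_tensor(node_features)
    Wn = norm_weights.data if isinstance(norm_weights, Tensor) else \
        np.asarray(norm_weights, dtype=float)
    act = ACTIVATIONS[activation]
    return act(Tensor(Wn) @ (h @ as_tensor(W)) + as_tensor(b))


def multi_hop_aggregate(node_features, norm_weights, params, n_hops: int,
                        activation: str = "relu", prefix: str = "gcn"):
    """Mix 0..K-hop aggregates with softmax hop weights.

    s^(0) is the input itself; s^(k) applies :func:`gcn_layer` with
    hop-k parameters to s^(k-1). Returns ``(mixed, hop_weights)``;
    with ``n_hops=0`` the mixture weight on s^(0) is forced to 1 and the
    input is returned unchanged.
    """
    if n_hops < 0:
        raise ValueError("n_hops must be >= 0")
    s = as_tensor(node_features)
    if n_hops == 0:
        return s, Tensor(np.ones(1))
    hops = [s]
    for k in range(1, n_hops + 1):
        s = gcn_layer(s, norm_weights, params[f"{prefix}.W{k}"],
                      params[f"{prefix}.b{k}"], activation)
        hops.append(s)
    alpha = softmax(params[f"{prefix}.hop_logits"], axis=-1)
    mixed = hops[0] * alpha[0]
    for k in range(1, n_hops + 1):
        mixed = mixed + hops[k] * alpha[k]
    return mixed, alpha
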