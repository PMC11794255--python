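"""Per-feature gated recurrent encoding of history windows, with
attention pooling.

Each feature's scalar series within a window is encoded independently by
a gated recurrent cell (shared parameters across features by default):

    g_t = sigmoid(W_g y_t + U_g z_{t-1} + b_g)        (forget gate)
    i_t = sigmoid(W_i y_t + U_i z_{t-1} + b_i)        (input gate)
    z_t = g_t * z_{t-1} + i_t * tanh(W_z y_t + U_z z_{t-1} + b_z)

This gate structure differs from a standard LSTM/GRU (no output gate,
forget and input gates are independent), so the cell is implemented
directly rather than borrowed.

Attention pooling scores states with q . tanh(Q_z z + c_z) and
normalizes with a softmax over the axis being summed, so the pooled
context is a convex combination of the states. The model pools the
feature axis this way; the lag axis is pooled by taking the final-lag
state (or by anomaly-aware attention when enabled).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, softmax, stack

__all__ = ["init_gated_cell", "init_attention", "gated_cell_step",
           "encode_sequence", "temporal_attention"]


def init_gated_cell(input_dim: int, hidden_dim: int, rng: np.random.Generator,
                    scale: float = 0.2, prefix: str = "cell"):
    """Parameter dict for one gated recurrent cell (Tensors with grad)."""
    p = {}
    for gate in ("g", "i", "z"):
        p[f"{prefix}.W_{gate}"] = Tensor(
            rng.normal(0, scale, (input_dim, hidden_dim)), requires_grad=True)
        p[f"{prefix}.U_{gate}"] = Tensor(
            rng.normal(0, scale, (hidden_dim, hidden_dim)), requires_grad=True)
        p[f"{prefix}.b_{gate}"] = Tensor(
            np.zeros(hidden_dim), requires_grad=True)
    return p


def init_attention(state_dim: int, attn_dim: int, rng: np.random.Generator,
                   scale: float = 0.2, prefix: str = "attn"):
    """Parameters of a tanh attention scorer: Q (proj), c (bias), q (score)."""
    return {
        f"{prefix}.Q": Tensor(rng.normal(0, scale, (state_dim, attn_dim)),
                              requires_grad=True),
        f"{prefix}.c": Tensor(np.zeros(attn_dim), requires_grad=True),
        f"{prefix}.q": Tensor(rng.normal(0, scale, (attn_dim, 1)),
                              requires_grad=True),
    }


def gated_cell_step(y, z_prev, params, prefix: str = "cell") -> Tensor:
    """One recurrence step; ``y`` (..., input_dim), ``z_prev`` (..., hidden)."""
    y, z_prev = as_tensor(y), as_tensor(z_prev)
    if y.shape[-1] != params[f"{prefix}.W_g"].shape[0]:
        raise ValueError("input dimension does not match cell parameters")
    g = (y @ params[f"{prefix}.W_g"] + z_prev @ params[f"{prefix}.U_g"]
         + params[f"{prefix}.b_g"]).sigmoid()
    i = (y @ params[f"{prefix}.W_i"] + z_prev @ params[f"{prefix}.U_i"]
         + params[f"{prefix}.b_i"]).sigmoid()
    cand = (y @ params[f"{prefix}.W_z"] + z_prev @ params[f"{prefix}.U_z"]
            + params[f"{prefix}.b_z"]).tanh()
    return g * z_prev + i * cand


def encode_sequence(history, params, n_layers: int = 1, prefix: str = "cell",
                    lag_axis: int = 0, dropout: float = 0.0,
                    rng: np.random.Generator | None = None,
                    train: bool = False) -> Tensor:
    """Run the gated cell over a window, oldest lag first.

    ``history`` carries lags along ``lag_axis`` and the cell input along
    the last axis — typically (batch, n_lags, regions, features, 1) with
    ``lag_axis=1``. All other axes are independent channels sharing the
    cell parameters. Layer ``l`` (parameters under ``{prefix}{l}``)
    consumes layer ``l-1``'s state sequence; the initial state is zero.
    Inverted dropout is applied to non-final layer outputs during
    training. Returns the last layer's states, stacked over lags with
    the input's layout (last axis = hidden_dim).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    seq = as_tensor(history)
    lag_axis = lag_axis % seq.ndim
    n_lags = seq.shape[lag_axis]
    hidden = params[f"{prefix}0.W_g"].shape[1]
    for layer in range(n_layers):
        pfx = f"{prefix}{layer}"
        state_shape = (seq.shape[:lag_axis] + seq.shape[lag_axis + 1:-1]
                       + (hidden,))
        z = Tensor(np.zeros(state_shape))
        states = []
        for lag in range(n_lags):
            y = seq[tuple([slice(None)] * lag_axis + [lag])]
            z = gated_cell_step(y, z, params, prefix=pfx)
            states.append(z)
        seq = stack(states, axis=lag_axis)
        if train and dropout > 0 and layer < n_layers - 1:
            if rng is None:
                raise ValueError("dropout during training needs an rng")
            mask = (rng.random(seq.shape) >= dropout) / (1.0 - dropout)
            seq = seq * Tensor(mask)
    return seq


def temporal_attention(states, params, prefix: str = "attn", axis: int = -2):
    """Attention-pool states over ``axis`` (default: the feature axis).

    Scores are q . tanh(Q z + c); weights are the softmax of the scores
    over the pooled axis, so the context is convex. Returns
    ``(weights, context)`` with the pooled axis removed from both.
    """
    z = as_tensor(states)
    axis = axis % z.ndim
    if axis != z.ndim - 2:
        z = z.swapaxes(axis, z.ndim - 2)
    scores = (z @ params[f"{prefix}.Q"] + params[f"{prefix}.c"]).tanh() \
        @ params[f"{prefix}.q"]                       # (..., n, 1)
    weights = softmax(scores, axis=-2)
    context = (weights * z).sum(axis=-2)
    w = weights[tuple([slice(None)] * (weights.ndim - 1) + [0])]
    return w, context
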