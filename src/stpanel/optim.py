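"""Optimization utilities: AdamW with decoupled weight decay, global
gradient-norm clipping, and a cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW", "clip_gradients", "cosine_lr", "global_grad_norm"]


class AdamW:
    """Adaptive moments with decoupled weight decay.

    Decay is applied directly to the parameters (not through the
    gradient), so it composes cleanly with any explicit ridge terms in
    the loss. Default decay is 0: the objective's own ridge penalties
    carry the regularization.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def global_grad_norm(params: dict[str, Tensor]) -> float:
    """L2 norm of the concatenated gradient across all parameter groups."""
    sq = 0.0
    for p in params.values():
        if p.grad is not None:
            sq += float(np.sum(p.grad ** 2))
    return float(np.sqrt(sq))


def clip_gradients(params: dict[str, Tensor], clip_norm: float):
    """Scale all gradients so their global norm is at most ``clip_norm``.

    Returns ``(pre_norm, post_norm)``.
    """
    pre = global_grad_norm(params)
    if pre > clip_norm > 0:
        scale = clip_norm / pre
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return pre, min(pre, clip_norm) if clip_norm > 0 else pre


def cosine_lr(lr0: float, epoch: int, max_epochs: int,
              lr_min_factor: float = 0.01) -> float:
    """Cosine annealing from lr0 down to lr0 * lr_min_factor."""
    lr_min = lr0 * lr_min_factor
    if max_epochs <= 1:
        return lr0
    frac = epoch / (max_epochs - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + np.cos(np.pi * frac))
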