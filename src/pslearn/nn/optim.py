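"""Adam optimizer and cosine learning-rate decay."""

from __future__ import annotations

import math

import numpy as np


def cosine_lr(base_lr: float, step: int, total_steps: int, min_frac: float = 0.05) -> float:
    """Cosine decay from ``base_lr`` to ``min_frac * base_lr`` over ``total_steps``."""
    if total_steps <= 1:
        return base_lr
    t = min(step, total_steps - 1) / (total_steps - 1)
    return base_lr * (min_frac + (1 - min_frac) * 0.5 * (1 + math.cos(math.pi * t)))


class Adam:
    """Adaptive-moment estimation over a named parameter dict.

    Updates are applied in place so the model's arrays stay shared with the
    optimizer.  Iteration order is the sorted parameter name order, which
    makes the update sequence (and hence the trained weights) deterministic.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(sorted(params.items()))
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k in self.params:
            g = grads.get(k)
            if g is None:
                continue
            g = g.astype(self.params[k].dtype, copy=False)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
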