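"""Minimal dense-network building blocks: fan-in initialization and the
Adam/AdamW optimizers.  Everything operates on plain float64 numpy arrays;
gradients are computed analytically by the owning model (see ``cvae``)."""

from __future__ import annotations

import numpy as np

__all__ = ["init_linear", "Adam"]


def init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Uniform fan-in initialization: W, b ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=fan_out)
    return W, b


class Adam:
    """Adam with optional decoupled weight decay (AdamW).

    Parameters are a list of numpy arrays updated in place.  With
    ``decoupled_weight_decay=True`` the decay is applied directly to the
    parameters (AdamW); otherwise ``weight_decay`` is added to the gradient
    (classical L2, unused by default).
    """

    def __init__(self, params: list, lr: float = 0.01, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 decoupled_weight_decay: bool = False):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled_weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay and self.decoupled:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
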