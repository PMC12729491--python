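"""AdamW with decoupled weight decay and the single-cycle cosine schedule."""

from __future__ import annotations

import numpy as np

from .nn import Parameter

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    """Adam with decoupled weight decay (weights shrink before the Adam step)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            p.data *= 1.0 - self.lr * self.weight_decay
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]


def cosine_lr(epoch: int, total_epochs: int, lr: float, lr_min: float) -> float:
    """Single half-cosine decay: lr at epoch 0, lr_min at the final epoch.

    lr(t) = lr_min + (lr - lr_min) * (1 + cos(pi * t / T)) / 2 with
    T = total_epochs - 1, so both endpoints are hit exactly.
    """
    if total_epochs <= 1:
        return lr
    t = min(max(epoch, 0), total_epochs - 1)
    return lr_min + (lr - lr_min) * (1.0 + np.cos(np.pi * t / (total_epochs - 1))) / 2.0
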