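"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay and an optional linear-decay schedule.

    With ``total_steps`` set, the learning rate ramps linearly from its
    initial value down to zero over the run (the schedule used for
    fine-tuning); otherwise it stays constant.
    """

    def __init__(self, params: list[Parameter], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01, total_steps: int | None = None):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def current_lr(self) -> float:
        if self.total_steps:
            return self.lr0 * max(0.0, 1.0 - self.t / self.total_steps)
        return self.lr0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr()
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                            + self.weight_decay * p.data)
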