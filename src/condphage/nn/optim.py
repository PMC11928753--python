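"""Adam optimizer with linear warmup/decay, in the decoupled-decay style."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


def linear_warmup_decay(step: int, base_lr: float, warmup: int, total: int) -> float:
    """Linear warmup to ``base_lr`` over ``warmup`` steps, then linear decay
    toward zero at ``total`` (floored at 10% of the base rate)."""
    if warmup > 0 and step < warmup:
        return base_lr * (step + 1) / warmup
    if total <= warmup:
        return base_lr
    frac = (total - step) / max(1, total - warmup)
    return base_lr * max(0.1, frac)


def _decays(name: str) -> bool:
    # biases and normalization scales are exempt from weight decay
    leaf = name.rsplit(".", 1)[-1]
    return leaf not in ("b", "gamma", "beta")


class Adam:
    def __init__(
        self,
        params: dict[str, Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {n: np.zeros_like(p.value) for n, p in params.items()}
        self._v = {n: np.zeros_like(p.value) for n, p in params.items()}

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, p in self.params.items():
            g = p.grad
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and _decays(name):
                update = update + self.weight_decay * p.value
            p.value -= lr * update
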