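"""Adam optimiser over :class:`~esunet.nn.layers.Param` lists."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with decoupled learning rate (set per step via ``lr``).

    Defaults follow the training setup used throughout the package:
    betas (0.9, 0.99), eps 1e-8, no weight decay.
    """

    def __init__(self, params: list[Param], betas: tuple[float, float] = (0.9, 0.99),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
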