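"""Adam optimizer with classic (gradient-coupled) L2 regularization.

L2 is added to the gradient before the moment updates, matching the usual
"L2Regularization" convention of mainstream training toolboxes rather than
decoupled weight decay.  Per-parameter learning-rate multipliers support a
faster-learning classification head.  Normalization scale/shift and biases
are exempt from L2.
"""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 3.0e-4,
        l2: float = 5.0e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if self.l2 and p.decay:
                g = g + self.l2 * p.value
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.value -= (self.lr * p.lr_mult) * mhat / (np.sqrt(vhat) + self.eps)
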