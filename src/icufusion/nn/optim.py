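"""AdamW with decoupled weight decay.

Weight decay is applied directly to the parameters (not folded into the
gradient), matching the decoupled formulation; LayerNorm gains/biases and
other one-dimensional parameters are exempt from decay, the convention
used when training transformers.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW"]


class AdamW:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1.0 - b1) * g
            self._v[i] = b2 * self._v[i] + (1.0 - b2) * g * g
            m_hat = self._m[i] / bc1
            v_hat = self._v[i] / bc2
            if self.weight_decay and p.data.ndim > 1:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
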