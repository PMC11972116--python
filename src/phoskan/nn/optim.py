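"""Adam optimizer with the training protocol's default moments."""

from __future__ import annotations

from typing import List

import numpy as np

from phoskan.nn.autograd import Tensor


class Adam:
    """Adam with bias-corrected first/second moment estimates.

    Defaults follow the training protocol: base step size 9e-4, first
    moment decay 0.9, second moment decay 0.999.
    """

    def __init__(self, params: List[Tensor], lr: float = 9e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < beta1 < 1 and 0 < beta2 < 1):
            raise ValueError("moment decays must lie in (0, 1)")
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, grad_scale: float = 1.0) -> None:
        """Apply one update; ``grad_scale`` divides incoming gradients
        (used to undo loss scaling in reduced-precision mode)."""
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad if grad_scale == 1.0 else p.grad / grad_scale
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
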