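"""LAMB optimizer (layer-wise adaptive moments) for the numpy transformer.

LAMB is Adam with a per-parameter trust ratio: the Adam update direction
is rescaled by ||w|| / ||update|| so that every layer takes a step
proportional to its own weight norm.  Constant learning rate, no warmup.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .autodiff import Tensor


class LAMB:
    def __init__(
        self,
        params: Dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple = (0.9, 0.999),
        eps: float = 1e-6,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1 ** self.t)
            v_hat = v / (1 - self.b2 ** self.t)
            update = m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay > 0:
                update = update + self.weight_decay * p.data
            w_norm = np.linalg.norm(p.data)
            u_norm = np.linalg.norm(update)
            trust = w_norm / u_norm if w_norm > 0 and u_norm > 0 else 1.0
            p.data -= self.lr * trust * update

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
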