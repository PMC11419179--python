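"""Minimal first-order optimizers (ascent convention)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam / AMSGrad with bias correction, stepping in the ascent
    direction.  ``lr_scale`` multiplies the base rate (used for decay
    schedules)."""

    def __init__(self, n_params: int, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, amsgrad: bool = False):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.amsgrad = amsgrad
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.vhat = np.zeros(n_params)
        self.t = 0

    def step(self, x: np.ndarray, grad: np.ndarray, lr_scale: float = 1.0) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        m_hat = self.m / (1 - self.beta1 ** self.t)
        if self.amsgrad:
            np.maximum(self.vhat, self.v, out=self.vhat)
            v_hat = self.vhat / (1 - self.beta2 ** self.t)
        else:
            v_hat = self.v / (1 - self.beta2 ** self.t)
        return x + self.lr * lr_scale * m_hat / (np.sqrt(v_hat) + self.eps)
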