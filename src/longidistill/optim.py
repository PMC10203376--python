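"""Gradient-descent optimizers for the autodiff parameter tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "SGD"]


class Adam:
    """Adaptive-moment estimation with optional per-parameter learning rates.

    ``param_groups`` is a list of (params, lr) pairs; a parameter whose
    group is currently frozen (see ``set_frozen``) is skipped entirely, so
    frozen weights stay bitwise unchanged.
    """

    def __init__(self, param_groups: list[tuple[list[Tensor], float]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.param_groups = [(list(ps), lr) for ps, lr in param_groups]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = {id(p): np.zeros_like(p.data) for ps, _ in self.param_groups for p in ps}
        self._v = {id(p): np.zeros_like(p.data) for ps, _ in self.param_groups for p in ps}
        self._t = {id(p): 0 for ps, _ in self.param_groups for p in ps}
        self._frozen: set[int] = set()

    @classmethod
    def single_group(cls, params: list[Tensor], lr: float, **kw) -> "Adam":
        return cls([(params, lr)], **kw)

    def set_frozen(self, group_indices: set[int]) -> None:
        self._frozen = set(group_indices)

    def zero_grad(self) -> None:
        for ps, _ in self.param_groups:
            for p in ps:
                p.grad = None

    def step(self) -> None:
        for gi, (ps, lr) in enumerate(self.param_groups):
            if gi in self._frozen:
                continue
            for p in ps:
                if p.grad is None:
                    continue
                k = id(p)
                self._t[k] += 1
                t = self._t[k]
                self._m[k] = self.beta1 * self._m[k] + (1 - self.beta1) * p.grad
                self._v[k] = self.beta2 * self._v[k] + (1 - self.beta2) * p.grad ** 2
                m_hat = self._m[k] / (1 - self.beta1 ** t)
                v_hat = self._v[k] / (1 - self.beta2 ** t)
                p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


class SGD:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
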