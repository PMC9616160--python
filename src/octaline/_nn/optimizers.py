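"""First-order optimizers with per-parameter state.

Defaults follow the values the deep-learning community treats as
canonical for each method; Adamax (the classifier's default) uses the
step size 0.002 from its original formulation.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, lr: float):
        self.lr = float(lr)
        self._state: dict[int, dict] = {}

    def _slot(self, i: int, param: np.ndarray, names: tuple[str, ...]) -> dict:
        if i not in self._state:
            self._state[i] = {n: np.zeros_like(param) for n in names}
        return self._state[i]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float = 0.01):
        super().__init__(lr)

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class Adagrad(Optimizer):
    def __init__(self, lr: float = 0.01, eps: float = 1e-7):
        super().__init__(lr)
        self.eps = eps

    def step(self, params, grads):
        for i, (p, g) in enumerate(zip(params, grads)):
            s = self._slot(i, p, ("acc",))
            s["acc"] += g * g
            p -= self.lr * g / (np.sqrt(s["acc"]) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho = rho
        self.eps = eps

    def step(self, params, grads):
        for i, (p, g) in enumerate(zip(params, grads)):
            s = self._slot(i, p, ("acc",))
            s["acc"][...] = self.rho * s["acc"] + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s["acc"]) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        bc1 = 1 - self.beta1 ** self.t
        bc2 = 1 - self.beta2 ** self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            s = self._slot(i, p, ("m", "v"))
            s["m"][...] = self.beta1 * s["m"] + (1 - self.beta1) * g
            s["v"][...] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
            p -= self.lr * (s["m"] / bc1) / (np.sqrt(s["v"] / bc2) + self.eps)


class Adamax(Optimizer):
    """Adam variant based on the infinity norm of past gradients."""

    def __init__(self, lr: float = 0.002, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        bc1 = 1 - self.beta1 ** self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            s = self._slot(i, p, ("m", "u"))
            s["m"][...] = self.beta1 * s["m"] + (1 - self.beta1) * g
            np.maximum(self.beta2 * s["u"], np.abs(g), out=s["u"])
            p -= (self.lr / bc1) * s["m"] / (s["u"] + self.eps)


OPTIMIZERS = {
    "adamax": Adamax,
    "adam": Adam,
    "adagrad": Adagrad,
    "sgd": SGD,
    "rmsprop": RMSprop,
}


def make_optimizer(name: str, lr: float | None = None) -> Optimizer:
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return OPTIMIZERS[key]() if lr is None else OPTIMIZERS[key](lr=lr)
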