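"""Optimizers (SGD, Adam, AdaBound) and the cosine-annealing schedule.

All optimizers operate on a flat parameter vector; the training loop
flattens and unflattens the nested parameter tree around each step.
AdaBound follows its reference formulation: Adam moments with per-element
step sizes clipped into a band that tightens around ``final_lr`` as
training progresses, so the method starts like Adam and ends like SGD.
"""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    pass


def cosine_annealing(lr0: float, epoch: int, total_epochs: int,
                     lr_min: float = 0.0) -> float:
    """Learning rate at ``epoch`` of a single cosine period (no restarts)."""
    t = min(max(epoch, 0), total_epochs)
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + np.cos(np.pi * t / total_epochs))


class SGD:
    def __init__(self, momentum: float = 0.9):
        self.momentum = momentum
        self.v = None

    def step(self, params, grads, lr):
        if self.v is None:
            self.v = np.zeros_like(params)
        self.v = self.momentum * self.v + grads
        return params - lr * self.v


class Adam:
    def __init__(self, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = self.v = None
        self.t = 0

    def step(self, params, grads, lr):
        if self.m is None:
            self.m = np.zeros_like(params)
            self.v = np.zeros_like(params)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grads
        self.v = self.b2 * self.v + (1 - self.b2) * grads ** 2
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return params - lr * mhat / (np.sqrt(vhat) + self.eps)


class AdaBound:
    """Adam with dynamically bounded per-element step sizes.

    The bound band [final_lr * (1 - 1/(gamma t + 1)),
    final_lr * (1 + 1/(gamma t))] converges to the SGD rate ``final_lr``.
    """

    def __init__(self, final_lr: float = 0.1, gamma: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 base_lr: float = 1e-3):
        self.final_lr = final_lr
        self.gamma = gamma
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.base_lr = base_lr  # scales final_lr with any lr schedule
        self.m = self.v = None
        self.t = 0

    def step(self, params, grads, lr):
        if self.m is None:
            self.m = np.zeros_like(params)
            self.v = np.zeros_like(params)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grads
        self.v = self.b2 * self.v + (1 - self.b2) * grads ** 2
        bias = np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        step_size = lr * bias
        final = self.final_lr * lr / self.base_lr
        lower = final * (1 - 1 / (self.gamma * self.t + 1))
        upper = final * (1 + 1 / (self.gamma * self.t))
        eta = np.clip(step_size / (np.sqrt(self.v) + self.eps), lower, upper)
        return params - eta * self.m


_OPTIMIZERS = {"sgd": SGD, "adam": Adam, "adabound": AdaBound}


def optimizer_factory(name: str, **kwargs):
    try:
        cls = _OPTIMIZERS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}"
        ) from None
    return cls(**kwargs)
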