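"""Optimization utilities: Adam, max-norm constraint, early stopping."""

from __future__ import annotations

import numpy as np

from .layers import Module, Parameter

__all__ = ["Adam", "apply_maxnorm", "EarlyStopper", "minibatches"]


class Adam:
    """Adam optimizer over a fixed list of parameters."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def apply_maxnorm(params: list[Parameter], c: float) -> None:
    """Clip weight norms to at most ``c`` after an update.

    Matrices are constrained per column (per incoming-weight vector of each
    unit, the Keras convention); vectors (biases) by their whole norm.
    """
    if c is None or c <= 0:
        return
    for p in params:
        if p.data.ndim >= 2:
            norms = np.sqrt((p.data**2).sum(axis=0, keepdims=True))
            factor = np.minimum(1.0, c / np.maximum(norms, 1e-12))
            p.data = p.data * factor
        else:
            norm = np.linalg.norm(p.data)
            if norm > c:
                p.data = p.data * (c / norm)


class EarlyStopper:
    """Track a monitored loss; stop after ``patience`` epochs without improvement."""

    def __init__(self, model: Module, patience: int = 10, min_delta: float = 0.0):
        self.model = model
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_state = model.state()
        self.bad_epochs = 0

    def update(self, loss: float) -> bool:
        """Record an epoch loss; return True when training should stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_state = self.model.state()
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience

    def restore_best(self) -> None:
        self.model.load_state(self.best_state)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index arrays covering ``range(n)``."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
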