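"""Parameterised layers and the Adam optimizer for the numpy networks."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Conv2d", "Adam", "he_init"]


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d:
    """3x3 (or kxk) convolution layer with bias, 'same' padding by default."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int = 3, zero_init: bool = False):
        fan_in = c_in * k * k
        if zero_init:
            w = np.zeros((k, k, c_in, c_out), dtype=np.float32)
        else:
            w = he_init(rng, (k, k, c_in, c_out), fan_in)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor, pad: int | None = None) -> Tensor:
        return conv2d(x, self.w, self.b, pad=pad)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class Adam:
    """Adam with bias correction; deterministic given a fixed update order."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(np.float32)
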