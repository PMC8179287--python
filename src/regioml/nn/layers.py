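"""Parameter containers and the Adam optimizer used by both networks."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, relu

__all__ = ["Linear", "MLP", "Adam", "glorot"]


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Linear:
    """Affine map ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x.matmul(self.W)
        if self.b is not None:
            out = out + self.b
        return out

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Feed-forward network with ReLU hidden layers and a linear output.

    ``hidden_of(x)`` exposes the activation of the last hidden layer, which
    the selectivity model uses as its latent reaction representation.
    """

    def __init__(self, sizes, rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def hidden_of(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = relu(layer(x))
        return x

    def __call__(self, x: Tensor) -> Tensor:
        return self.layers[-1](self.hidden_of(x))

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_params(self):
        return self.params
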