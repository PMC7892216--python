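"""Minimal dense-network machinery: activations, MLP blocks, Adam.

The dose model is a small fixed graph of fully connected subnets (about
1200 parameters in total), so the implementation is a direct NumPy one:
each subnet caches its forward pass and backpropagates both parameter
gradients and the gradient with respect to its inputs, which lets subnets
be chained into an arbitrary feed-forward DAG.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ACTIVATIONS", "MLP", "Adam"]

_SELU_SCALE = 1.0507009873554804934193349852946
_SELU_ALPHA = 1.6732632423543772848170429916717


def _selu(x):
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))


def _selu_grad(x):
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(x))


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(float)


def _softplus(x):
    # log(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def _softplus_grad(x):
    return 1.0 / (1.0 + np.exp(-x))


def _linear(x):
    return x


def _linear_grad(x):
    return np.ones_like(x)


ACTIVATIONS = {
    "selu": (_selu, _selu_grad),
    "elu": (_elu, _elu_grad),
    "relu": (_relu, _relu_grad),
    "softplus": (_softplus, _softplus_grad),
    "linear": (_linear, _linear_grad),
}


class MLP:
    """A fully connected block with one activation name per layer.

    ``sizes`` is ``[n_in, hidden..., n_out]``; ``activations`` has one
    entry per non-input layer.  Weights are initialised uniformly in
    ``[-init_range, init_range]``, biases at zero.
    """

    def __init__(self, sizes, activations, rng, init_range: float = 0.05):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per non-input layer")
        for name in activations:
            if name not in ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")
        self.sizes = list(sizes)
        self.activations = list(activations)
        self.W = [rng.uniform(-init_range, init_range, size=(m, n))
                  for m, n in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(n) for n in sizes[1:]]
        self._cache = None

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        zs, hs = [], [x]
        h = x
        for w, b, act in zip(self.W, self.b, self.activations):
            z = h @ w + b
            h = ACTIVATIONS[act][0](z)
            if cache:
                zs.append(z)
                hs.append(h)
        if cache:
            self._cache = (zs, hs)
        return h

    def backward(self, grad_out: np.ndarray):
        """Backpropagate ``dL/d(output)``; returns (dW, db, dL/d(input))."""
        if self._cache is None:
            raise RuntimeError("forward(cache=True) must precede backward")
        zs, hs = self._cache
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        g = grad_out
        for layer in range(len(self.W) - 1, -1, -1):
            g = g * ACTIVATIONS[self.activations[layer]][1](zs[layer])
            dW[layer] = hs[layer].T @ g
            db[layer] = g.sum(axis=0)
            g = g @ self.W[layer].T
        return dW, db, g

    def params(self):
        return self.W + self.b

    def grads_in_order(self, dW, db):
        return dW + db


class Adam:
    """Adam optimiser over a flat list of parameter arrays."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
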