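"""Minimal numpy neural-network stack used by the transfer-learning fitness.

Implements exactly what the training objective needs: feed-forward layers
with backprop, the six categorical loss functions, and the eleven
first-order optimizers selectable by the hyperparameter encoding.  Losses
are computed on softmax probabilities; gradients are propagated through the
softmax analytically.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "PoolFlatten",
    "Dropout",
    "softmax",
    "loss_value_and_dz",
    "LOSS_NAMES",
    "make_optimizer",
    "OPTIMIZER_NAMES",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    """Feed-forward layer with cached forward pass and explicit backprop."""

    trainable: bool = True

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> Optional[np.ndarray]:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad_out):
        self.grads = {
            "W": self._x.T @ grad_out,
            "b": grad_out.sum(axis=0),
        }
        return grad_out @ self.params["W"].T


class ReLU(Layer):
    trainable = False

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class PoolFlatten(Layer):
    """Block-average pool an image batch to ``p x p x C`` and flatten.

    Fixed front-end of the tiny backbone; has no parameters and nothing
    upstream of it needs gradients.
    """

    trainable = False

    def __init__(self, pool: int = 8):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        b, h, w, c = x.shape
        p = self.pool
        rows = np.array_split(np.arange(h), p)
        cols = np.array_split(np.arange(w), p)
        out = np.empty((b, p, p, c))
        for i, ri in enumerate(rows):
            band = x[:, ri]
            for j, cj in enumerate(cols):
                out[:, i, j] = band[:, :, cj].mean(axis=(1, 2))
        return out.reshape(b, -1)

    def backward(self, grad_out):
        return None  # first layer; no upstream gradient needed

    @property
    def output_dim(self):
        return self.pool * self.pool * 3


class Dropout(Layer):
    trainable = False

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


# -- losses ---------------------------------------------------------------

LOSS_NAMES = (
    "Categorical Crossentropy",
    "Categorical Hinge",
    "KLDivergence",
    "Poisson",
    "Squared Hinge",
    "Hinge",
)

_EPS = 1e-12


def _dz_from_dp(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    # gradient through softmax: dz = p * (dp - sum(dp * p))
    return p * (dp - (dp * p).sum(axis=1, keepdims=True))


def loss_value_and_dz(name: str, y: np.ndarray, p: np.ndarray):
    """Loss value and its gradient w.r.t. the pre-softmax logits.

    ``y`` is one-hot, ``p`` the softmax output, both ``(B, K)``.
    """
    b, k = y.shape
    if name in ("Categorical Crossentropy", "KLDivergence"):
        value = float(-(y * np.log(p + _EPS)).sum() / b)
        if name == "KLDivergence":
            value += float((y * np.log(y + _EPS)).sum() / b)  # constant term
        return value, (p - y) / b
    if name == "Poisson":
        value = float((p - y * np.log(p + _EPS)).mean())
        dp = (1.0 - y / (p + _EPS)) / (b * k)
        return value, _dz_from_dp(p, dp)
    if name in ("Hinge", "Squared Hinge"):
        ypm = 2.0 * y - 1.0
        margin = np.maximum(0.0, 1.0 - ypm * p)
        if name == "Hinge":
            value = float(margin.mean())
            dp = -ypm * (margin > 0) / (b * k)
        else:
            value = float((margin**2).mean())
            dp = -2.0 * ypm * margin / (b * k)
        return value, _dz_from_dp(p, dp)
    if name == "Categorical Hinge":
        pos = (y * p).sum(axis=1, keepdims=True)
        neg_masked = np.where(y > 0, -np.inf, p)
        neg_idx = neg_masked.argmax(axis=1)
        neg = p[np.arange(b), neg_idx][:, None]
        margin = np.maximum(0.0, 1.0 - pos + neg)
        value = float(margin.mean())
        active = (margin > 0).astype(float)
        dp = -y * active / b
        dp[np.arange(b), neg_idx] += active[:, 0] / b
        return value, _dz_from_dp(p, dp)
    raise ValueError(f"unknown loss {name!r}")


# -- optimizers -----------------------------------------------------------

OPTIMIZER_NAMES = (
    "Adam",
    "NAdam",
    "AdaGrad",
    "AdaDelta",
    "AdaMax",
    "RMSProp",
    "SGD",
    "Ftrl",
    "SGD Nesterov",
    "RMSProp Centered",
    "Adam AMSGrad",
)

# Desk-scale step sizes: tuned for few-epoch training of a small softmax
# head, larger than the deep-learning library defaults on purpose.
_DEFAULT_LR = {
    "Adam": 0.02,
    "NAdam": 0.02,
    "AdaGrad": 0.05,
    "AdaDelta": 1.0,
    "AdaMax": 0.02,
    "RMSProp": 0.01,
    "SGD": 0.05,
    "Ftrl": 0.1,
    "SGD Nesterov": 0.05,
    "RMSProp Centered": 0.01,
    "Adam AMSGrad": 0.02,
}


class _Optimizer:
    def __init__(self, name: str, lr: float):
        self.name = name
        self.lr = lr
        self.state: Dict[int, dict] = {}
        self.t = 0

    def begin_step(self):
        self.t += 1

    def _st(self, key, param, **arrays):
        if key not in self.state:
            self.state[key] = {k: np.zeros_like(param) for k in arrays}
        return self.state[key]

    def update(self, key, param: np.ndarray, grad: np.ndarray) -> None:
        lr, t, eps = self.lr, self.t, 1e-8
        n = self.name
        if n == "SGD":
            param -= lr * grad
        elif n == "SGD Nesterov":
            s = self._st(key, param, v=0)
            mu = 0.9
            s["v"] = mu * s["v"] - lr * grad
            param += mu * s["v"] - lr * grad
        elif n in ("Adam", "Adam AMSGrad", "NAdam"):
            s = self._st(key, param, m=0, v=0, vhat=0)
            b1, b2 = 0.9, 0.999
            s["m"] = b1 * s["m"] + (1 - b1) * grad
            s["v"] = b2 * s["v"] + (1 - b2) * grad**2
            mhat = s["m"] / (1 - b1**t)
            vhat = s["v"] / (1 - b2**t)
            if n == "Adam AMSGrad":
                s["vhat"] = np.maximum(s["vhat"], vhat)
                vhat = s["vhat"]
            if n == "NAdam":
                mhat = b1 * mhat + (1 - b1) * grad / (1 - b1**t)
            param -= lr * mhat / (np.sqrt(vhat) + eps)
        elif n == "AdaMax":
            s = self._st(key, param, m=0, u=0)
            b1, b2 = 0.9, 0.999
            s["m"] = b1 * s["m"] + (1 - b1) * grad
            s["u"] = np.maximum(b2 * s["u"], np.abs(grad))
            param -= lr / (1 - b1**t) * s["m"] / (s["u"] + eps)
        elif n == "AdaGrad":
            s = self._st(key, param, acc=0)
            s["acc"] += grad**2
            param -= lr * grad / (np.sqrt(s["acc"]) + eps)
        elif n == "AdaDelta":
            s = self._st(key, param, acc=0, delta=0)
            rho = 0.95
            s["acc"] = rho * s["acc"] + (1 - rho) * grad**2
            step = np.sqrt(s["delta"] + eps) / np.sqrt(s["acc"] + eps) * grad
            s["delta"] = rho * s["delta"] + (1 - rho) * step**2
            param -= lr * step
        elif n in ("RMSProp", "RMSProp Centered"):
            s = self._st(key, param, acc=0, mg=0)
            rho = 0.9
            s["acc"] = rho * s["acc"] + (1 - rho) * grad**2
            denom = s["acc"]
            if n == "RMSProp Centered":
                s["mg"] = rho * s["mg"] + (1 - rho) * grad
                denom = s["acc"] - s["mg"] ** 2
            param -= lr * grad / (np.sqrt(denom) + eps)
        elif n == "Ftrl":
            s = self._st(key, param, z=0, n=0)
            sigma = (np.sqrt(s["n"] + grad**2) - np.sqrt(s["n"])) / lr
            s["z"] += grad - sigma * param
            s["n"] += grad**2
            param[...] = -lr * s["z"] / (np.sqrt(s["n"]) + eps)
        else:  # pragma: no cover
            raise ValueError(f"unknown optimizer {n!r}")


def make_optimizer(name: str, lr: Optional[float] = None) -> _Optimizer:
    if name not in OPTIMIZER_NAMES:
        raise ValueError(f"unknown optimizer {name!r}; expected one of {OPTIMIZER_NAMES}")
    return _Optimizer(name, lr if lr is not None else _DEFAULT_LR[name])
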