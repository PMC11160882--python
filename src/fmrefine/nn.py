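"""Neural-network forward model: phi -> J via a one-hidden-layer MLP.

The dihedral is embedded on the unit circle, x = (cos phi, sin phi), which
makes predictions 360-degree periodic and continuous across +-180.  The
network is a fully connected 2 -> n_hidden -> 1 map with GELU activations,
LeCun-normal initialisation, implemented directly in numpy with hand-written
reverse-mode gradients (the architecture is small enough that no autodiff
framework is needed).  An Adam optimiser for the weight updates lives here
too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["nn_embed", "NNForwardModel", "Adam"]

_DEG = np.pi / 180.0
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def nn_embed(phi_deg):
    """Sine-cosine embedding (cos phi, sin phi); shape ``phi.shape + (2,)``."""
    x = np.asarray(phi_deg, dtype=float) * _DEG
    return np.stack([np.cos(x), np.sin(x)], axis=-1)


def _gelu(z):
    from scipy.special import erf
    return 0.5 * z * (1.0 + erf(z / _SQRT2))


def _gelu_grad(z):
    from scipy.special import erf
    cdf = 0.5 * (1.0 + erf(z / _SQRT2))
    return cdf + z * _INV_SQRT_2PI * np.exp(-0.5 * z * z)


class NNForwardModel:
    """One-hidden-layer GELU network predicting a scalar coupling from phi."""

    def __init__(self, n_hidden: int = 200, seed: int = 0, zero_init: bool = False):
        self.n_hidden = n_hidden
        rng = np.random.default_rng(seed)
        if zero_init:
            self.W1 = np.zeros((2, n_hidden))
            self.W2 = np.zeros((n_hidden, 1))
        else:
            # LeCun normal: std = 1/sqrt(fan_in)
            self.W1 = rng.normal(0.0, 1.0 / np.sqrt(2.0), size=(2, n_hidden))
            self.W2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=(n_hidden, 1))
        self.b1 = np.zeros(n_hidden)
        self.b2 = np.zeros(1)

    @property
    def params(self) -> dict:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def predict(self, phi_deg) -> np.ndarray:
        """Forward pass; returns J (Hz) with the shape of ``phi_deg``."""
        phi = np.asarray(phi_deg, dtype=float)
        x = nn_embed(phi).reshape(-1, 2)
        z1 = x @ self.W1 + self.b1
        out = _gelu(z1) @ self.W2 + self.b2
        return out.reshape(phi.shape) if phi.shape else float(out[0, 0])

    def predict_and_cache(self, phi_deg):
        """Forward pass keeping intermediates for :meth:`backward`."""
        phi = np.asarray(phi_deg, dtype=float)
        x = nn_embed(phi).reshape(-1, 2)
        z1 = x @ self.W1 + self.b1
        h = _gelu(z1)
        out = (h @ self.W2 + self.b2).reshape(phi.shape)
        return out, (x, z1, h, phi.shape)

    def backward(self, cache, upstream) -> dict:
        """Gradients of sum_i upstream_i * J_i w.r.t. the weights."""
        x, z1, h, shape = cache
        u = np.asarray(upstream, dtype=float).reshape(-1, 1)
        gW2 = h.T @ u
        gb2 = u.sum(axis=0)
        dh = u @ self.W2.T
        dz1 = dh * _gelu_grad(z1)
        gW1 = x.T @ dz1
        gb1 = dz1.sum(axis=0)
        return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}

    def save(self, path):
        np.savez(path, **self.params)

    @classmethod
    def load(cls, path) -> "NNForwardModel":
        data = np.load(path)
        model = cls(n_hidden=data["W1"].shape[1], zero_init=True)
        model.W1, model.b1 = data["W1"], data["b1"]
        model.W2, model.b2 = data["W2"], data["b2"]
        return model


@dataclass
class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict, grads: dict) -> None:
        self._t += 1
        for key, p in params.items():
            g = grads[key].reshape(p.shape)
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1 ** self._t)
            vhat = v / (1 - self.beta2 ** self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
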