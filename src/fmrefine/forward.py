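"""Karplus forward model, parameter gradients and replica averaging.

The three-bond scalar coupling across a dihedral phi is modelled by the
Karplus relation

    3J(phi) = A cos^2(phi + phi0) + B cos(phi + phi0) + C,

with a coupling-type specific phase offset phi0.  The model is affine in
theta = (A, B, C), so its parameter gradient is independent of theta and its
theta-Hessian vanishes.  Angles are accepted in degrees at the API boundary
and converted once to radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "KarplusParams",
    "CouplingType",
    "coupling_type_registry",
    "karplus_predict",
    "karplus_param_grad",
    "karplus_basis",
    "replica_average",
]

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class KarplusParams:
    """Karplus coefficients (Hz) and phase offset (degrees)."""

    A: float
    B: float
    C: float
    phi0: float = 0.0

    def __post_init__(self):
        if not all(np.isfinite([self.A, self.B, self.C, self.phi0])):
            raise ValueError("Karplus parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C], dtype=float)

    @classmethod
    def from_array(cls, abc, phi0: float = 0.0) -> "KarplusParams":
        a, b, c = (float(x) for x in abc)
        return cls(A=a, B=b, C=c, phi0=phi0)


@dataclass(frozen=True)
class CouplingType:
    """Named coupling type with its conventional phase offset (degrees)."""

    name: str
    phi0: float


def coupling_type_registry() -> dict:
    """Registry of standard backbone couplings (name -> CouplingType)."""
    text = resources.files("fmrefine").joinpath("data/coupling_types.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: CouplingType(name=name, phi0=float(phi0))
            for name, phi0 in raw.items()}


def karplus_basis(phi_deg, phi0: float = 0.0):
    """Return (cos^2(phi+phi0), cos(phi+phi0)) evaluated elementwise."""
    x = np.cos((np.asarray(phi_deg, dtype=float) + phi0) * _DEG)
    return x * x, x


def karplus_predict(phi_deg, theta: KarplusParams):
    """3J(phi) in Hz; elementwise over phi (degrees), 360-degree periodic."""
    c2, c1 = karplus_basis(phi_deg, theta.phi0)
    return theta.A * c2 + theta.B * c1 + theta.C


def karplus_param_grad(phi_deg, theta: KarplusParams):
    """Gradient (d3J/dA, d3J/dB, d3J/dC) = (cos^2, cos, 1); theta-independent.

    Returns an array of shape ``phi.shape + (3,)``.
    """
    c2, c1 = karplus_basis(phi_deg, theta.phi0)
    return np.stack([c2, c1, np.ones_like(c1)], axis=-1)


def replica_average(states, ens, theta: KarplusParams, sem_convention: str = "sqrt_n"):
    """Replica-averaged predictions and finite-sampling error.

    ``states`` are the conformational-state indices of the N replicas; the
    mean prediction per observable is (1/N) sum_r J(phi[X_r, j]).  The
    finite-sampling error is the standard error of the mean,
    sample stdev / sqrt(N) (``sem_convention="sqrt_n"``, default), or the
    population stdev across replicas (``"population"``), which does not
    shrink with N.  N = 1 yields sem = 0 by convention.
    """
    states = np.asarray(states, dtype=int)
    if states.ndim != 1 or states.size < 1:
        raise ValueError("states must be a non-empty 1-D index array")
    if states.min() < 0 or states.max() >= ens.n_states:
        raise IndexError("replica state index out of range")
    g = karplus_predict(ens.phi[states, :], theta)  # (N, n_obs)
    n = states.size
    mean = g.mean(axis=0)
    if n == 1:
        sem = np.zeros_like(mean)
    elif sem_convention == "sqrt_n":
        sem = g.std(axis=0, ddof=1) / np.sqrt(n)
    elif sem_convention == "population":
        sem = g.std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown sem_convention {sem_convention!r}")
    return mean, sem
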