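"""Negative-log-posterior energy functions and their theta-gradients.

Two likelihood models are provided for replica-averaged predictions g versus
experimental values d:

* Gaussian: every observable shares the effective variance
  sigma0^2 = sigma_B^2 + sigma_SEM^2 combining experimental (Bayesian)
  uncertainty and finite-replica sampling error.

* Good-Bad: an outlier-robust two-component mixture in which "good"
  observables have variance sigma0^2 and "bad" ones an inflated variance
  (phi sigma0)^2 with phi >= 1; the unknown bad fraction is marginalised
  analytically, leaving phi as a sampled nuisance parameter.  At phi = 1 the
  Good-Bad energy reduces exactly to the Gaussian one.

Energies are in nats.  Nuisance parameters carry truncated Jeffreys priors
(p ~ 1/sigma on a bounded support) so that the xi = 0 reference evidence is
finite.  The replica count N multiplies the data term (the replica-averaged
likelihood is raised to the power N), making the energy extensive in
replicas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "UncertaintyState",
    "LikelihoodConfig",
    "goodbad_energy",
    "gaussian_energy",
    "energy",
    "energy_theta_grad",
    "log_nuisance_priors",
    "data_term",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class UncertaintyState:
    """Nuisance parameters of the likelihood.

    ``sigma_sem`` may be a scalar or a per-observable vector (the SEM is
    defined per observable); ``sigma0 = sqrt(sigma_b^2 + sigma_sem^2)`` is
    derived, guaranteeing sigma0 >= sigma_sem.
    """

    sigma_b: float
    sigma_sem: float | np.ndarray = 0.0
    phi_scale: float = 1.0

    def __post_init__(self):
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if np.any(np.asarray(self.sigma_sem) < 0):
            raise ValueError("sigma_sem must be >= 0")
        if self.phi_scale < 1.0:
            raise ValueError("phi_scale must be >= 1")

    @property
    def sigma0(self):
        return np.sqrt(self.sigma_b ** 2 + np.asarray(self.sigma_sem, float) ** 2)


@dataclass
class LikelihoodConfig:
    """Model choice, nuisance-prior supports and printed-form conventions."""

    model: str = "good_bad"  # "good_bad" | "gaussian"
    sigma_b_bounds: tuple = (0.05, 10.0)
    phi_bounds: tuple = (1.0, 20.0)
    heaviside_at_zero: float = 0.0
    #: second mixture component prefactor: "half" = 1/2 (the form obtained by
    #: marginalizing the bad fraction with normalized Gaussian components;
    #: default), "half_phi" = 1/(2 phi) (an extra ln(phi) penalty per outlier
    #: that prevents the heavy-tailed component from ever engaging).
    eq9_prefactor: str = "half"
    #: "population": sigma_SEM is the stdev of the per-replica predictions (the
    #: printed form); it floors the effective uncertainty at the replica spread,
    #: which regularises the mixture likelihood against the degenerate
    #: small-sigma spike.  "sqrt_n": sample stdev / sqrt(N) (shrinks with N).
    sem_convention: str = "population"

    def __post_init__(self):
        if self.model not in ("good_bad", "gaussian"):
            raise ValueError(f"unknown likelihood model {self.model!r}")
        for lo, hi in (self.sigma_b_bounds, self.phi_bounds):
            if not (0 < lo <= hi):
                raise ValueError("bounds must be positive and ordered")
        if self.eq9_prefactor not in ("half_phi", "half"):
            raise ValueError(f"unknown eq9_prefactor {self.eq9_prefactor!r}")


def _heaviside(x, at_zero):
    return np.where(x > 0, 1.0, np.where(x < 0, 0.0, at_zero))


def _log_normal(r, sigma):
    return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (r / sigma) ** 2


def _check_shapes(d, g):
    d = np.asarray(d, dtype=float)
    g = np.asarray(g, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("d must be a non-empty 1-D vector")
    if g.shape != d.shape:
        raise ValueError(f"d and g shapes differ: {d.shape} vs {g.shape}")
    return d, g


def _goodbad_log_mix(r, u_state, config):
    """Per-observable log of the Good-Bad mixture likelihood, plus weights."""
    sigma0 = np.broadcast_to(u_state.sigma0, r.shape).astype(float)
    if np.any(sigma0 <= 0):
        raise ValueError("sigma0 must be positive")
    sem = np.broadcast_to(np.asarray(u_state.sigma_sem, float), r.shape)
    phi = u_state.phi_scale
    h0 = config.heaviside_at_zero
    pre_good = (1.0 - _heaviside(sem - sigma0, h0)) / 2.0
    pre_bad = (1.0 - _heaviside(sem - phi * sigma0, h0)) / 2.0
    if config.eq9_prefactor == "half_phi":
        pre_bad = pre_bad / phi
    with np.errstate(divide="ignore"):
        t_good = np.log(pre_good) + _log_normal(r, sigma0)
        t_bad = np.log(pre_bad) + _log_normal(r, phi * sigma0)
    log_mix = logsumexp(np.stack([t_good, t_bad]), axis=0)
    # responsibility-weighted inverse variances, used by the theta-gradient
    w = (np.exp(t_good - log_mix) / sigma0 ** 2
         + np.exp(t_bad - log_mix) / (phi * sigma0) ** 2)
    return log_mix, w


def log_nuisance_priors(u_state: UncertaintyState, config: LikelihoodConfig) -> float:
    """Truncated Jeffreys log prior: -ln sigma_B - ln phi within bounds, -inf outside."""
    lo, hi = config.sigma_b_bounds
    plo, phi_hi = config.phi_bounds
    if not (lo <= u_state.sigma_b <= hi):
        return -np.inf
    if not (plo <= u_state.phi_scale <= phi_hi):
        return -np.inf
    return float(-np.log(u_state.sigma_b) - np.log(u_state.phi_scale))


def data_term(d, g, u_state, n_replicas, config=None) -> float:
    """Likelihood part of the energy: -N sum_j ln L_j (nats)."""
    config = config or LikelihoodConfig()
    d, g = _check_shapes(d, g)
    r = d - g
    if config.model == "gaussian":
        sigma0 = np.broadcast_to(u_state.sigma0, r.shape).astype(float)
        if np.any(sigma0 <= 0):
            raise ValueError("sigma0 must be positive")
        log_like = _log_normal(r, sigma0)
    else:
        log_like, _ = _goodbad_log_mix(r, u_state, config)
    return float(-n_replicas * np.sum(log_like))


def goodbad_energy(d, g, u_state, n_replicas, log_prior_states=0.0,
                   config=None) -> float:
    """Full Good-Bad energy u = -ln p(X, sigma0, phi, theta | D) (nats).

    ``log_prior_states`` is sum_r ln p(X_r) for the current replica states.
    """
    config = config or LikelihoodConfig(model="good_bad")
    u = -float(log_prior_states)
    u += data_term(d, g, u_state, n_replicas,
                   LikelihoodConfig(**{**config.__dict__, "model": "good_bad"}))
    return u - log_nuisance_priors(u_state, config)


def gaussian_energy(d, g, u_state, n_replicas, log_prior_states=0.0,
                    config=None) -> float:
    """Gaussian-likelihood energy (the phi = 1 limit of the Good-Bad model).

    The nuisance prior enters once, unscaled by the replica count, so this
    matches :func:`goodbad_energy` at phi = 1 exactly.
    """
    config = config or LikelihoodConfig(model="gaussian")
    u = -float(log_prior_states)
    u += data_term(d, g, u_state, n_replicas,
                   LikelihoodConfig(**{**config.__dict__, "model": "gaussian"}))
    return u - log_nuisance_priors(u_state, config)


def energy(d, g, u_state, n_replicas, log_prior_states=0.0, config=None) -> float:
    """Dispatch on ``config.model``."""
    config = config or LikelihoodConfig()
    fn = goodbad_energy if config.model == "good_bad" else gaussian_energy
    return fn(d, g, u_state, n_replicas, log_prior_states, config)


def energy_theta_grad(d, g, dg_dtheta, u_state, n_replicas, config=None) -> np.ndarray:
    """Analytic gradient of the data term w.r.t. the forward-model parameters.

    ``dg_dtheta`` has shape (n_obs, m).  The uncertainty state is held fixed
    (the SEM's dependence on theta is neglected, as in the printed gradient).
    For the Gaussian model (or phi = 1) this reduces to
    -N sum_j (dg_j/dtheta_i) (d_j - g_j) / sigma0^2.
    """
    config = config or LikelihoodConfig()
    d, g = _check_shapes(d, g)
    dg = np.asarray(dg_dtheta, dtype=float)
    if dg.shape[0] != d.size:
        raise ValueError("dg_dtheta first axis must match the observable count")
    r = d - g
    if config.model == "gaussian" or u_state.phi_scale == 1.0:
        sigma0 = np.broadcast_to(u_state.sigma0, r.shape).astype(float)
        w = r / sigma0 ** 2
    else:
        _, winv = _goodbad_log_mix(r, u_state, config)
        w = r * winv
    return -n_replicas * (dg.T @ w)
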