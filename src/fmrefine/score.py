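"""Free-energy score for forward-model quality.

The score f(theta) = -ln Z(theta)/Z0 is the free energy of switching the
experimental restraints on: a family of posteriors is built by raising the
likelihood to a power xi in [0, 1] (priors untouched), chains are run at a
schedule of xi values, and the end-to-end free-energy difference is
estimated with MBAR from the pooled samples.  Because the energy is linear
in xi given a sample's (prior, data) decomposition, u_xi = prior + xi*data,
the full cross-state reduced-energy matrix is available at no extra cost.

The score is extensive in the replica count; the reduced score f/N_r is
reported alongside.  Its theta-gradient is the posterior (xi = 1) average
of the energy gradient, estimated from the same sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .likelihood import LikelihoodConfig
from .mbar import mbar_solve, overlap_adjacent
from .sampler import SamplerConfig, run_chain

__all__ = ["XiSchedule", "ScoreResult", "xi_energy", "optimize_xi_schedule",
           "compute_score", "score_theta_gradient"]


@dataclass(frozen=True)
class XiSchedule:
    """Strictly increasing xi values spanning [0, 1]."""

    values: tuple = tuple(np.linspace(0.0, 1.0, 11))

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size < 2 or v[0] != 0.0 or v[-1] != 1.0 or np.any(np.diff(v) <= 0):
            raise ValueError("schedule must increase strictly from 0 to 1")

    def __len__(self):
        return len(self.values)

    @classmethod
    def uniform(cls, n: int = 11) -> "XiSchedule":
        return cls(values=tuple(np.linspace(0.0, 1.0, n)))


@dataclass
class ScoreResult:
    """BICePs score with its MBAR statistical error and diagnostics."""

    f: float                    #: -ln Z(theta)/Z0 (nats)
    stat_err: float
    n_replicas: int
    xi_values: tuple
    per_xi_f: np.ndarray        #: free energy of each intermediate vs xi=0
    overlap_min: float
    grad: np.ndarray | None = None       #: d f / d theta at xi = 1
    grad_err: np.ndarray | None = None
    n_samples: int = 0
    warnings: list = field(default_factory=list)

    @property
    def reduced_f(self) -> float:
        return self.f / self.n_replicas


def xi_energy(prior_term: float, data_term: float, xi: float) -> float:
    """u_xi = prior + xi * data; the xi = 1 endpoint is the full energy."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    return float(prior_term) + float(xi) * float(data_term)


def _sample_xi(ens, data, theta, xi, sampler_config, likelihood, seed,
               collect_grad=False, predictions=None):
    cfg = replace(sampler_config, seed=seed, sample_theta=False,
                  collect_grad=collect_grad)
    trace, _ = run_chain(ens, data, cfg, likelihood,
                         init_thetas=np.atleast_2d(theta), xi=xi,
                         predictions=predictions)
    return trace


def optimize_xi_schedule(ens, data, theta, n_xi: int = 11,
                         sampler_config: SamplerConfig | None = None,
                         likelihood: LikelihoodConfig | None = None,
                         seed: int = 0, rounds: int = 3,
                         rel_tol: float = 0.10) -> XiSchedule:
    """Space xi values equidistantly in estimated thermodynamic length.

    The local length density is approximated by the per-xi standard
    deviation of du/dxi (= the data term) from short pilot chains; the
    cumulative trapezoid of that density is inverted by monotone
    interpolation, iterating until per-interval lengths agree within
    ``rel_tol`` (at most ``rounds`` re-pilots).  A flat density (constant
    likelihood) degenerates to uniform spacing.
    """
    likelihood = likelihood or LikelihoodConfig()
    base = sampler_config or SamplerConfig(n_replicas=8)
    pilot = replace(base, burn_steps=max(200, base.burn_steps // 10),
                    prod_steps=max(500, base.prod_steps // 10), thin=5)
    xi = np.linspace(0.0, 1.0, n_xi)
    for rnd in range(max(1, rounds)):
        sd = np.empty_like(xi)
        for i, x in enumerate(xi):
            tr = _sample_xi(ens, data, theta, x, pilot, likelihood,
                            seed=seed + 101 * rnd + i)
            sd[i] = tr.data_term.std()
        if not np.any(sd > 0):
            return XiSchedule.uniform(n_xi)
        dens = np.maximum(sd, 1e-12)
        seg = 0.5 * (dens[1:] + dens[:-1]) * np.diff(xi)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if cum[-1] == 0:
            return XiSchedule.uniform(n_xi)
        lengths = np.diff(cum)
        if lengths.max() - lengths.min() <= rel_tol * lengths.mean():
            break
        targets = np.linspace(0.0, cum[-1], n_xi)
        xi_new = np.interp(targets, cum, xi)
        xi_new[0], xi_new[-1] = 0.0, 1.0
        # keep strictly increasing
        for i in range(1, n_xi):
            xi_new[i] = max(xi_new[i], xi_new[i - 1] + 1e-6)
        xi = np.minimum(xi_new, 1.0)
        xi[-1] = 1.0
    return XiSchedule(values=tuple(xi))


def compute_score(ens, data, theta, schedule: XiSchedule | None = None,
                  sampler_config: SamplerConfig | None = None,
                  likelihood: LikelihoodConfig | None = None,
                  seed: int = 0, n_boot: int = 32,
                  want_grad: bool = False, predictions=None) -> ScoreResult:
    """BICePs score for a fixed theta by MBAR over the xi schedule.

    Each intermediate runs its own chain over (X, sigma_B, phi) with theta
    held fixed; the pooled (prior, data) pairs give the cross-xi energy
    matrix analytically.  The statistical error is a bootstrap over per-xi
    sample resampling.  ``want_grad`` additionally returns the xi = 1
    Boltzmann-averaged energy gradient (the score's theta-gradient).
    """
    schedule = schedule or XiSchedule.uniform(11)
    likelihood = likelihood or LikelihoodConfig()
    cfg = sampler_config or SamplerConfig(n_replicas=32, burn_steps=1000,
                                          prod_steps=5000, thin=5)
    xis = np.asarray(schedule.values)
    K = len(xis)
    priors, datas, N_k = [], [], []
    warnings = []
    grad = grad_err = None
    for i, x in enumerate(xis):
        tr = _sample_xi(ens, data, theta, x, cfg, likelihood,
                        seed=seed + 7919 * i,
                        collect_grad=(want_grad and x == 1.0),
                        predictions=predictions)
        priors.append(tr.prior_term)
        datas.append(tr.data_term)
        N_k.append(len(tr))
        if want_grad and x == 1.0:
            gs = tr.grad[:, 0, :]             # single theta set
            m = gs.shape[0]
            if m < 100:
                warnings.append("fewer than 100 samples for the gradient")
            grad = gs.mean(axis=0)
            grad_err = gs.std(axis=0, ddof=1) / np.sqrt(m)
    prior_n = np.concatenate(priors)
    data_n = np.concatenate(datas)
    N_k = np.array(N_k, dtype=float)
    u_kn = prior_n[None, :] + xis[:, None] * data_n[None, :]
    res = mbar_solve(u_kn, N_k)
    if not res.converged:
        warnings.append("MBAR solver did not report convergence")
    f = float(res.f_k[-1])
    # bootstrap over samples within each xi state
    rng = np.random.default_rng(seed + 424243)
    bounds = np.concatenate([[0], np.cumsum(N_k).astype(int)])
    fs = []
    for _ in range(n_boot):
        idx = np.concatenate([
            rng.integers(bounds[k], bounds[k + 1], size=int(N_k[k]))
            for k in range(K)])
        rb = mbar_solve(u_kn[:, idx], N_k, f_init=res.f_k)
        fs.append(rb.f_k[-1])
    stat_err = float(np.std(fs, ddof=1)) if n_boot > 1 else np.nan
    try:
        omin = float(overlap_adjacent(u_kn, N_k.astype(int), res.f_k).min())
    except Exception:
        omin = np.nan
    return ScoreResult(f=f, stat_err=stat_err, n_replicas=cfg.n_replicas,
                       xi_values=tuple(xis), per_xi_f=res.f_k.copy(),
                       overlap_min=omin, grad=grad, grad_err=grad_err,
                       n_samples=int(N_k.sum()), warnings=warnings)


def score_theta_gradient(ens, data, theta,
                         sampler_config: SamplerConfig | None = None,
                         likelihood: LikelihoodConfig | None = None,
                         seed: int = 0):
    """d f / d theta = <du/dtheta> over the xi = 1 posterior (theta fixed).

    Returns ``(grad, stderr)``; flags in stderr are NaN when fewer than 100
    samples were available.
    """
    likelihood = likelihood or LikelihoodConfig()
    cfg = sampler_config or SamplerConfig(n_replicas=32, burn_steps=1000,
                                          prod_steps=5000, thin=5)
    tr = _sample_xi(ens, data, theta, 1.0, cfg, likelihood, seed=seed,
                    collect_grad=True)
    gs = tr.grad[:, 0, :]
    m = gs.shape[0]
    grad = gs.mean(axis=0)
    err = gs.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.full(3, np.nan)
    if m < 100:
        err = np.full(3, np.nan)
    return grad, err
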