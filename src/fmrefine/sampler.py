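"""MCMC over the joint posterior of replica states, nuisance parameters and
forward-model (Karplus) parameters.

A sweep proposes, in order: one uniform state re-assignment per replica,
a log-space random walk on each sigma_B, a reflected random walk on each
variance scale phi, and a theta move.  During burn-in the theta proposal is
drifted along the negative energy gradient (stochastic-gradient style); the
drift is switched off for production so that proposals are symmetric and the
chain satisfies detailed balance.  All randomness is pre-generated from a
single Generator, so traces are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forward import karplus_basis
from .likelihood import LikelihoodConfig

__all__ = [
    "SamplerConfig",
    "ReplicaSystem",
    "Trace",
    "propose_theta",
    "run_chain",
    "gelman_rubin",
    "posterior_summary",
]

_MODEL_FLAG = {"gaussian": 0, "good_bad": 1}
_SEM_MODE = {"sqrt_n": 0, "population": 1}
_PREFAC = {"half_phi": 0, "half": 1}


@dataclass
class SamplerConfig:
    """Knobs of the replica MCMC sampler."""

    n_replicas: int = 32
    burn_steps: int = 10_000
    prod_steps: int = 50_000
    lrate: float | str = "auto"      #: burn-in gradient drift; "auto" scales 1e-4
    eta: float = 0.01                #: stdev of the Gaussian theta proposal (Hz)
    sigma_step: float = 0.05         #: log-space step width for sigma_B
    phi_step: float = 0.10           #: step width for the variance scale phi
    seed: int = 0
    thin: int = 1
    gradient_on_during_burn_only: bool = True
    sample_theta: bool = True
    sample_sigma: bool = True
    sample_phi: bool = True
    sample_states: bool = True
    state_attempts: int = 1
    sigma_b_init: float | None = None
    phi_init: float = 10.0
    phi_frozen_during_burn: bool = True
    collect_grad: bool = False
    record_aux: bool = False

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.burn_steps < 0 or self.prod_steps < 0:
            raise ValueError("step counts must be >= 0")
        if self.eta < 0 or (self.lrate != "auto" and self.lrate < 0):
            raise ValueError("lrate and eta must be >= 0")


def propose_theta(theta_old, grad_u, lrate, eta, rng):
    """Gradient-drifted Gaussian proposal theta - lrate*grad + eta*N(0,1)."""
    theta_old = np.asarray(theta_old, dtype=float)
    grad_u = np.asarray(grad_u, dtype=float)
    z = rng.standard_normal(theta_old.shape) if eta > 0 else np.zeros_like(theta_old)
    return theta_old - lrate * grad_u + eta * z


class ReplicaSystem:
    """MCMC state vector: replica assignments, theta per set, nuisances.

    Observables are sorted so that each forward-model set occupies a
    contiguous block; per-state Karplus basis matrices are precomputed.
    """

    def __init__(self, ens, data, thetas, likelihood: LikelihoodConfig,
                 n_replicas: int, set_idx=None, phi0=None,
                 sigma_b_init=None, phi_init=1.0, xi: float = 1.0,
                 predictions=None):
        d = np.asarray(data, dtype=float)
        if d.ndim != 1 or d.size != ens.n_observables:
            raise ValueError("data length must match the observable count")
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        self.K = thetas.shape[0]
        if thetas.shape[1] != 3:
            raise ValueError("each theta set must be (A, B, C)")
        if not np.all(np.isfinite(thetas)):
            raise ValueError("initial theta must be finite")
        set_idx = (np.zeros(d.size, dtype=np.int64) if set_idx is None
                   else np.asarray(set_idx, dtype=np.int64))
        if set_idx.max() >= self.K or set_idx.min() < 0:
            raise ValueError("set_idx out of range")
        phi0 = np.zeros(self.K) if phi0 is None else np.asarray(phi0, dtype=float)
        if not 0.0 <= xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")

        order = np.argsort(set_idx, kind="stable")
        self.order = order
        self.d = d[order]
        self.set_idx = set_idx[order]
        self.obs_lo = np.searchsorted(self.set_idx, np.arange(self.K)).astype(np.int64)
        self.obs_hi = np.searchsorted(self.set_idx, np.arange(self.K),
                                      side="right").astype(np.int64)

        phi = ens.phi[:, order]
        self.C2 = np.empty_like(phi)
        self.C1 = np.empty_like(phi)
        for k in range(self.K):
            sl = slice(self.obs_lo[k], self.obs_hi[k])
            c2, c1 = karplus_basis(phi[:, sl], phi0[k])
            self.C2[:, sl] = c2
            self.C1[:, sl] = c1

        self.ens = ens
        self.likelihood = likelihood
        self.N = int(n_replicas)
        self.xi = float(xi)
        self.theta = thetas.copy()
        lo, hi = likelihood.sigma_b_bounds
        if sigma_b_init is None:
            sigma_b_init = float(np.clip(1.0, lo, hi))
        self.sigma_b = np.full(self.K, float(np.clip(sigma_b_init, lo, hi)))
        plo, phi_hi_b = likelihood.phi_bounds
        self.phi_sc = np.full(self.K, float(np.clip(phi_init, plo, phi_hi_b)))
        if likelihood.model == "gaussian":
            self.phi_sc[:] = 1.0

        # fixed per-state predictions (e.g. a neural forward model) bypass
        # the Karplus basis; theta moves must then stay disabled
        self._G_fixed = None
        if predictions is not None:
            P = np.asarray(predictions, dtype=float)
            if P.shape != ens.phi.shape:
                raise ValueError("predictions must be (n_states, n_obs)")
            self._G_fixed = P[:, order]

        with np.errstate(divide="ignore"):
            self.logp_state = np.log(ens.populations)
        # replicas start spread deterministically over the states
        self.states = (np.arange(self.N) % ens.n_states).astype(np.int64)
        self._rebuild_caches()

    def _rebuild_caches(self):
        self.counts = np.bincount(self.states,
                                  minlength=self.ens.n_states).astype(np.int64)
        if self._G_fixed is not None:
            self.G = self._G_fixed.copy()
        else:
            self.G = np.empty_like(self.C2)
            for k in range(self.K):
                sl = slice(self.obs_lo[k], self.obs_hi[k])
                self.G[:, sl] = (self.theta[k, 0] * self.C2[:, sl]
                                 + self.theta[k, 1] * self.C1[:, sl]
                                 + self.theta[k, 2])
        self.G2 = self.G ** 2
        cf = self.counts.astype(float)
        self.S1 = cf @ self.G
        self.S2 = cf @ self.G2
        self.T2 = cf @ self.C2
        self.T1 = cf @ self.C1

    # -- energies -----------------------------------------------------------
    def data_energy(self) -> float:
        w = np.empty_like(self.d)
        cfg = self.likelihood
        return float(_kernels.data_term_kernel(
            self.S1, self.S2, self.d, self.set_idx, self.sigma_b, self.phi_sc,
            self.N, _MODEL_FLAG[cfg.model], _SEM_MODE[cfg.sem_convention],
            _PREFAC[cfg.eq9_prefactor], w, False))

    def prior_energy(self) -> float:
        ps = -float(self.logp_state[self.states].sum())
        pn = float(np.log(self.sigma_b).sum() + np.log(self.phi_sc).sum())
        return ps + pn

    def total_energy(self) -> float:
        return self.prior_energy() + self.xi * self.data_energy()


@dataclass
class Trace:
    """Production-phase record of one chain."""

    theta: np.ndarray          # (n_rec, K, 3)
    sigma_b: np.ndarray        # (n_rec, K)
    phi_scale: np.ndarray      # (n_rec, K)
    energy: np.ndarray         # (n_rec,)
    prior_term: np.ndarray     # (n_rec,)
    data_term: np.ndarray      # (n_rec,)
    grad: np.ndarray | None = None      # (n_rec, K, 3) if collected
    weights: np.ndarray | None = None   # (n_rec, n_obs) if collected
    counts: np.ndarray | None = None    # (n_rec, n_states) if collected
    occupancy: np.ndarray | None = None
    acceptance: dict = field(default_factory=dict)
    xi: float = 1.0
    n_replicas: int = 1
    seed: int = 0

    def __len__(self):
        return self.energy.shape[0]

    def to_dataframe(self):
        import pandas as pd
        rows = []
        n, K, _ = self.theta.shape
        for k in range(K):
            df = pd.DataFrame({
                "step": np.arange(n), "set": k,
                "A": self.theta[:, k, 0], "B": self.theta[:, k, 1],
                "C": self.theta[:, k, 2], "sigma_B": self.sigma_b[:, k],
                "phi_scale": self.phi_scale[:, k], "energy": self.energy,
                "acc_rate_theta": self.acceptance.get("theta", np.nan),
                "acc_rate_sigma": self.acceptance.get("sigma", np.nan),
            })
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _sweep_phase(sys: ReplicaSystem, n_sweeps, cfg: SamplerConfig, rng,
                 grad_on, lrate, thin, collect_grad, record_aux):
    """Run one phase (burn or production) through the compiled kernel."""
    lcfg = sys.likelihood
    K, N = sys.K, sys.N
    n_rec = n_sweeps // thin
    n_obs = sys.d.size
    out_theta = np.empty((n_rec, K, 3))
    out_sigma = np.empty((n_rec, K))
    out_phi = np.empty((n_rec, K))
    out_energy = np.empty(n_rec)
    out_prior = np.empty(n_rec)
    out_data = np.empty(n_rec)
    out_grad = np.empty((n_rec, K, 3) if collect_grad else (1, K, 3))
    out_w = np.empty((n_rec, n_obs) if record_aux else (1, n_obs))
    out_counts = np.zeros((n_rec, sys.ens.n_states) if record_aux
                          else (1, sys.ens.n_states), dtype=np.int64)
    occ = np.zeros(sys.ens.n_states, dtype=np.int64)
    acc = np.zeros((4, 2), dtype=np.int64)

    chunk = 20_000
    done = 0
    while done < n_sweeps:
        m = min(chunk, n_sweeps - done)
        r_state_u = rng.random((m, N))
        r_state_acc = rng.random((m, N))
        r_sig_z = rng.standard_normal((m, K))
        r_sig_acc = rng.random((m, K))
        r_phi_z = rng.standard_normal((m, K))
        r_phi_acc = rng.random((m, K))
        r_th_z = rng.standard_normal((m, K, 3))
        r_th_acc = rng.random((m, K))
        # views into the output arrays for this chunk (thin divides chunk)
        lo = done // thin
        hi = (done + m) // thin
        _kernels.run_sweeps(
            m, sys.ens.n_states, N, K, sys.xi,
            sys.C2, sys.C1, sys.G, sys.G2, sys.states, sys.counts,
            sys.S1, sys.S2, sys.T2, sys.T1,
            sys.d, sys.set_idx, sys.obs_lo, sys.obs_hi,
            sys.logp_state, sys.theta, sys.sigma_b, sys.phi_sc,
            _MODEL_FLAG[lcfg.model], _SEM_MODE[lcfg.sem_convention],
            _PREFAC[lcfg.eq9_prefactor],
            lcfg.sigma_b_bounds[0], lcfg.sigma_b_bounds[1],
            lcfg.phi_bounds[0], lcfg.phi_bounds[1],
            cfg.sample_states, cfg.sample_sigma, cfg.sample_phi,
            cfg.sample_theta, grad_on,
            lrate, cfg.eta, cfg.sigma_step, cfg.phi_step,
            thin, collect_grad, record_aux,
            r_state_u, r_state_acc, r_sig_z, r_sig_acc,
            r_phi_z, r_phi_acc, r_th_z, r_th_acc,
            out_theta[lo:hi], out_sigma[lo:hi], out_phi[lo:hi],
            out_energy[lo:hi], out_prior[lo:hi], out_data[lo:hi],
            out_grad[lo:hi] if collect_grad else out_grad,
            out_w[lo:hi] if record_aux else out_w,
            out_counts[lo:hi] if record_aux else out_counts,
            occ, acc)
        done += m

    names = ("states", "sigma", "phi", "theta")
    acceptance = {nm: (acc[i, 0] / acc[i, 1] if acc[i, 1] else np.nan)
                  for i, nm in enumerate(names)}
    return Trace(theta=out_theta, sigma_b=out_sigma, phi_scale=out_phi,
                 energy=out_energy, prior_term=out_prior, data_term=out_data,
                 grad=out_grad if collect_grad else None,
                 weights=out_w if record_aux else None,
                 counts=out_counts if record_aux else None,
                 occupancy=occ, acceptance=acceptance, xi=sys.xi,
                 n_replicas=N, seed=cfg.seed)


def _auto_lrate(sys: ReplicaSystem, cap_step=0.3) -> float:
    """1e-4 scaled so the initial drift step never exceeds ``cap_step`` Hz."""
    w = np.empty_like(sys.d)
    lcfg = sys.likelihood
    _kernels.data_term_kernel(
        sys.S1, sys.S2, sys.d, sys.set_idx, sys.sigma_b, sys.phi_sc, sys.N,
        _MODEL_FLAG[lcfg.model], _SEM_MODE[lcfg.sem_convention],
        _PREFAC[lcfg.eq9_prefactor], w, True)
    g = np.empty((sys.K, 3))
    _kernels.theta_grad_kernel(sys.T2, sys.T1, w, sys.set_idx, sys.N, sys.K,
                               sys.xi, g)
    ginf = np.max(np.abs(g))
    if ginf == 0 or not np.isfinite(ginf):
        return 1e-4
    return float(min(1e-4, cap_step / ginf))


def run_chain(ens, data, config: SamplerConfig,
              likelihood: LikelihoodConfig | None = None,
              init_thetas=((0.0, 0.0, 0.0),), set_idx=None, phi0=None,
              xi: float = 1.0, sample_theta: bool | None = None,
              predictions=None):
    """Burn-in (gradient-assisted) then production (symmetric proposals).

    Returns ``(trace, summary)`` where the trace covers production only and
    the summary holds per-set posterior means/stdevs of (A, B, C, sigma_B,
    phi).  Raises if the initial energy is not finite.
    """
    likelihood = likelihood or LikelihoodConfig()
    if sample_theta is not None:
        from dataclasses import replace as _rep
        config = _rep(config, sample_theta=sample_theta)
    sys = ReplicaSystem(ens, data, init_thetas, likelihood, config.n_replicas,
                        set_idx=set_idx, phi0=phi0,
                        sigma_b_init=config.sigma_b_init,
                        phi_init=config.phi_init, xi=xi,
                        predictions=predictions)
    if predictions is not None and config.sample_theta:
        raise ValueError("theta sampling requires the Karplus forward model")
    if not np.isfinite(sys.total_energy()):
        raise ValueError("initial energy is not finite; check inputs")
    rng = np.random.default_rng(config.seed)
    lrate = _auto_lrate(sys) if config.lrate == "auto" else float(config.lrate)
    grad_burn = config.gradient_on_during_burn_only
    if config.burn_steps:
        burn_cfg = config
        if config.phi_frozen_during_burn:
            from dataclasses import replace as _rep2
            burn_cfg = _rep2(config, sample_phi=False)
        _sweep_phase(sys, config.burn_steps, burn_cfg, rng,
                     grad_on=grad_burn and config.sample_theta, lrate=lrate,
                     thin=max(1, config.thin), collect_grad=False,
                     record_aux=False)
    trace = _sweep_phase(sys, config.prod_steps, config, rng,
                         grad_on=False, lrate=0.0, thin=max(1, config.thin),
                         collect_grad=config.collect_grad,
                         record_aux=config.record_aux)
    # incremental running sums vs full recomputation (drift check)
    ed_cached = sys.data_energy()
    sys._rebuild_caches()
    ed_fresh = sys.data_energy()
    if abs(ed_cached - ed_fresh) > 1e-6 * max(1.0, abs(ed_fresh)):
        raise RuntimeError("cached energy drifted from full recomputation")
    summary = posterior_summary(trace)
    summary["populations"] = trace.occupancy / max(1, trace.occupancy.sum())
    return trace, summary


def gelman_rubin(chains) -> np.ndarray:
    """Gelman-Rubin R-hat across chains of equal length.

    ``chains`` is a sequence of 1-D parameter series (one per chain), or 2-D
    arrays (chain, draws) handled column-wise.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    m, n = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return np.sqrt((n - 1) / n) if B == 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def posterior_summary(trace: Trace, map_bins: int = 64) -> dict:
    """Means, stdevs, histogram-mode MAP and theta covariance per set."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    th = trace.theta
    n, K, _ = th.shape

    def _map(x):
        if x.min() == x.max():
            return float(x[0])
        hist, edges = np.histogram(x, bins=map_bins)
        i = int(np.argmax(hist))
        return 0.5 * (edges[i] + edges[i + 1])

    out = {
        "theta_mean": th.mean(axis=0),
        "theta_std": th.std(axis=0, ddof=1) if n > 1 else np.zeros((K, 3)),
        "theta_map": np.array([[_map(th[:, k, i]) for i in range(3)]
                               for k in range(K)]),
        "theta_cov": np.array([np.cov(th[:, k, :].T) if n > 1
                               else np.zeros((3, 3)) for k in range(K)]),
        "sigma_b_mean": trace.sigma_b.mean(axis=0),
        "sigma_b_map": np.array([_map(trace.sigma_b[:, k]) for k in range(K)]),
        "phi_mean": trace.phi_scale.mean(axis=0),
        "phi_map": np.array([_map(trace.phi_scale[:, k]) for k in range(K)]),
        "acceptance": trace.acceptance,
    }
    return out
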