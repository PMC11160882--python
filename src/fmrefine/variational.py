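"""Variational minimisation of the free-energy score over forward models.

Karplus coefficients are optimised with bounded L-BFGS-B using the
posterior-averaged energy gradient; parameter uncertainty comes from the
finite-difference Hessian of the score at the optimum (inverse Hessian =
covariance, when positive definite).  The same score serves as the training
loss for the neural forward model: each epoch re-samples the nuisance
posterior (states, sigma_B, phi) at the current predictions, and the
network weights follow the Boltzmann-averaged energy gradient through the
chain rule, updated with Adam.  Sampling sigma each epoch is the implicit
regulariser - it adapts the sharpness of the loss as the fit improves.

Objective noise is tamed with common random numbers: every score
evaluation inside one optimisation run reuses the same chain seeds, making
the objective a deterministic (if slightly biased) function of theta that
quasi-Newton methods can line-search reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .likelihood import LikelihoodConfig
from .nn import Adam, NNForwardModel
from .sampler import SamplerConfig, run_chain
from .score import XiSchedule, compute_score

__all__ = ["OptResult", "minimize_score", "hessian_covariance",
           "train_nn_forward", "NNTrainConfig"]

#: generous physical ranges for Karplus coefficients (Hz)
THETA_BOUNDS = ((0.0, 15.0), (-10.0, 10.0), (-5.0, 10.0))


@dataclass
class OptResult:
    """Outcome of one or more variational runs."""

    theta_star: np.ndarray              # (n_runs, 3)
    f_star: np.ndarray                  # (n_runs,)
    theta_mean: np.ndarray              # (3,)
    theta_std: np.ndarray               # (3,) across runs
    trajectories: list = field(default_factory=list)
    covariance: np.ndarray | None = None
    hessian_flag: str = ""
    n_runs: int = 1


def _variational_sampler(n_replicas, eval_steps, n_xi):
    prod = max(50, eval_steps // n_xi)
    return SamplerConfig(n_replicas=n_replicas, burn_steps=max(50, prod // 5),
                         prod_steps=prod, thin=2)


def minimize_score(ens, data, init_thetas=((9.0, -1.0, 1.0), (4.0, 0.0, 3.0),
                                           (0.0, 0.0, 0.0)),
                   schedule: XiSchedule | None = None,
                   likelihood: LikelihoodConfig | None = None,
                   n_replicas: int = 4, eval_steps: int = 10_000,
                   seed: int = 0, maxfun: int = 40,
                   with_hessian: bool = False) -> OptResult:
    """L-BFGS-B minimisation of the score from several disperse starts.

    ``eval_steps`` production MCMC steps are spent per objective
    evaluation, split across the xi intermediates.  Runs are aggregated by
    averaging the per-run optima (mean +- std across runs).
    """
    schedule = schedule or XiSchedule.uniform(11)
    likelihood = likelihood or LikelihoodConfig()
    cfg = _variational_sampler(n_replicas, eval_steps, len(schedule))
    init_thetas = np.atleast_2d(np.asarray(init_thetas, dtype=float))
    thetas, fs, trajs = [], [], []
    for run, th0 in enumerate(init_thetas):
        run_seed = seed + 50021 * run
        traj = []

        def objective(th):
            res = compute_score(ens, data, th, schedule, cfg, likelihood,
                                seed=run_seed, n_boot=0, want_grad=True)
            if not np.isfinite(res.f):
                raise FloatingPointError("score evaluation returned non-finite")
            traj.append((th.copy(), res.f, float(np.linalg.norm(res.grad))))
            return res.f, res.grad

        opt = minimize(objective, th0, jac=True, method="L-BFGS-B",
                       bounds=THETA_BOUNDS,
                       options={"maxfun": maxfun, "ftol": 1e-8, "gtol": 1e-3})
        thetas.append(opt.x)
        fs.append(opt.fun)
        trajs.append(traj)
    thetas = np.array(thetas)
    fs = np.array(fs)
    if not np.any(np.isfinite(fs)):
        raise RuntimeError("all variational runs diverged")
    result = OptResult(theta_star=thetas, f_star=fs,
                       theta_mean=thetas.mean(axis=0),
                       theta_std=(thetas.std(axis=0, ddof=1)
                                  if len(thetas) > 1 else np.zeros(3)),
                       trajectories=trajs, n_runs=len(thetas))
    if with_hessian:
        cov, flag = hessian_covariance(ens, data, result.theta_mean, schedule,
                                       likelihood, n_replicas=n_replicas,
                                       eval_steps=eval_steps, seed=seed + 999)
        result.covariance = cov
        result.hessian_flag = flag
    return result


def hessian_covariance(ens, data, theta_star, schedule=None, likelihood=None,
                       n_replicas: int = 4, eval_steps: int = 10_000,
                       step: float = 0.05, repeats: int = 3, seed: int = 0):
    """Covariance = inverse of the finite-difference score Hessian.

    Central differences with ``step`` Hz per component, averaged over
    ``repeats`` independent seeds to beat Monte-Carlo noise.  Returns
    ``(covariance, flag)``; a non-positive-definite or singular Hessian is
    flagged and no inverse is reported.
    """
    schedule = schedule or XiSchedule.uniform(11)
    likelihood = likelihood or LikelihoodConfig()
    cfg = _variational_sampler(n_replicas, eval_steps, len(schedule))
    theta_star = np.asarray(theta_star, dtype=float)
    m = theta_star.size
    H = np.zeros((m, m))
    for rep in range(repeats):
        s = seed + 7 * rep

        def f(th):
            return compute_score(ens, data, th, schedule, cfg, likelihood,
                                 seed=s, n_boot=0).f

        f0 = f(theta_star)
        Hr = np.zeros((m, m))
        e = np.eye(m) * step
        fp = [f(theta_star + e[i]) for i in range(m)]
        fm = [f(theta_star - e[i]) for i in range(m)]
        for i in range(m):
            Hr[i, i] = (fp[i] - 2 * f0 + fm[i]) / step ** 2
            for j in range(i + 1, m):
                fpp = f(theta_star + e[i] + e[j])
                fmm = f(theta_star - e[i] - e[j])
                Hr[i, j] = Hr[j, i] = (
                    fpp - fp[i] - fp[j] - fm[i] - fm[j] + fmm + 2 * f0
                ) / (2 * step ** 2)
        H += Hr / repeats
    eig = np.linalg.eigvalsh(H)
    if eig.min() <= 0:
        return None, "hessian not positive definite"
    return np.linalg.inv(H), ""


@dataclass
class NNTrainConfig:
    """Training schedule for the neural forward model."""

    epochs: int = 2000
    lr: float = 1e-3
    n_replicas: int = 4
    sweeps_per_epoch: int = 100      #: nuisance-posterior sweeps per epoch
    burn_per_epoch: int = 50
    thin: int = 10
    sample_sigma: bool = True        #: False freezes sigma (ablation)
    seed: int = 0
    grad_norm_max: float = 1e3       #: larger triggers a learning-rate backoff
    score_every: int = 0             #: >0: full multi-xi score every so many epochs


def train_nn_forward(ens, data, model: NNForwardModel,
                     config: NNTrainConfig | None = None,
                     likelihood: LikelihoodConfig | None = None):
    """Train the network with the restraint free energy as the loss.

    Each epoch: (1) forward-pass the per-state predictions, (2) run a short
    chain over (states, sigma_B, phi) with those predictions fixed,
    (3) accumulate the Boltzmann-averaged gradient of the energy through
    the network (chain rule via the per-state upstream weights) and
    (4) take an Adam step.  Returns ``(model, history)`` where the history
    holds the per-epoch energy loss and gradient norms (and periodic full
    scores if requested).
    """
    config = config or NNTrainConfig()
    likelihood = likelihood or LikelihoodConfig()
    opt = Adam(lr=config.lr)
    sigma_b, phi_sc = 1.0, 10.0
    losses, grad_norms, scores = [], [], []
    lr_scale = 1.0
    theta_dummy = np.zeros((1, 3))
    for epoch in range(config.epochs):
        preds, cache = model.predict_and_cache(ens.phi)
        cfg = SamplerConfig(
            n_replicas=config.n_replicas, burn_steps=config.burn_per_epoch,
            prod_steps=config.sweeps_per_epoch, thin=config.thin,
            seed=config.seed + epoch, sample_theta=False,
            sample_sigma=config.sample_sigma, record_aux=True,
            sigma_b_init=sigma_b, phi_init=phi_sc,
            phi_frozen_during_burn=False)
        trace, summ = run_chain(ens, data, cfg, likelihood,
                                init_thetas=theta_dummy, predictions=preds)
        # warm-start the nuisance state for the next epoch
        if config.sample_sigma:
            sigma_b = float(summ["sigma_b_mean"][0])
        phi_sc = float(summ["phi_mean"][0])
        losses.append(float(trace.energy.mean()))
        # du/dG[s, j] = -w_j * counts_s, averaged over recorded sweeps
        w_bar = trace.weights                        # (n_rec, n_obs)
        c_bar = trace.counts.astype(float)           # (n_rec, n_states)
        upstream = -np.einsum("rs,rj->sj", c_bar, w_bar) / len(trace)
        grads = model.backward(cache, upstream)
        gnorm = float(np.sqrt(sum(np.sum(g * g) for g in grads.values())))
        grad_norms.append(gnorm)
        if gnorm > config.grad_norm_max:
            lr_scale *= 0.5
            opt.lr = config.lr * lr_scale
        opt.step(model.params, grads)
        if config.score_every and (epoch + 1) % config.score_every == 0:
            res = compute_score(ens, data, (0.0, 0.0, 0.0),
                                XiSchedule.uniform(11),
                                SamplerConfig(n_replicas=config.n_replicas,
                                              burn_steps=200, prod_steps=800,
                                              thin=4, sample_theta=False),
                                likelihood, seed=config.seed + 90001 + epoch,
                                predictions=model.predict(ens.phi))
            scores.append((epoch + 1, res.f))
    history = {"loss": np.array(losses), "grad_norm": np.array(grad_norms),
               "scores": scores}
    return model, history
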