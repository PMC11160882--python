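"""Model/Results interface for Karplus-coefficient refinement.

`KarplusModel` bundles an ensemble (per-state dihedrals plus prior
populations) with experimental ensemble-averaged couplings and a
likelihood choice.  ``fit()`` samples the joint posterior over replica
states, nuisance uncertainties and the coefficients (several chains,
averaged, with Gelman-Rubin diagnostics); ``fit(method="variational")``
minimises the restraint free energy instead; ``fit(method="svd")`` runs
the population-weighted SVD baseline.  ``score(theta)`` evaluates the
free-energy score of a fixed coefficient set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import KarplusParams
from .likelihood import LikelihoodConfig
from .sampler import SamplerConfig, gelman_rubin, run_chain
from .score import ScoreResult, XiSchedule, compute_score
from .svd import svd_fit
from .variational import OptResult, minimize_score

__all__ = ["KarplusModel", "KarplusPosteriorResults", "KarplusVariationalResults",
           "KarplusSVDResults", "DEFAULT_INITS"]

#: disperse chain starting points for (A, B, C)
DEFAULT_INITS = ((9.0, -1.0, 1.0), (4.0, 0.0, 3.0), (0.0, 0.0, 0.0))


class KarplusModel:
    """Karplus-coefficient refinement against ensemble-averaged couplings."""

    def __init__(self, observables, ensemble, likelihood=None,
                 n_replicas: int = 32, phi0: float = 0.0):
        self.data = np.asarray(observables, dtype=float)
        self.ensemble = ensemble
        if self.data.shape != (ensemble.n_observables,):
            raise ValueError("observables must be one value per ensemble column")
        self.likelihood = likelihood or LikelihoodConfig()
        self.n_replicas = int(n_replicas)
        self.phi0 = float(phi0)

    @classmethod
    def from_dataframes(cls, obs_df, ens_df, pop_df=None, **kw):
        """Build from tidy tables (see the io module for the column layout)."""
        from .io import tables_to_arrays
        data, ens = tables_to_arrays(obs_df, ens_df, pop_df)
        return cls(data, ens, **kw)

    # ------------------------------------------------------------------
    def fit(self, method: str = "posterior", **kw):
        if method == "posterior":
            return self._fit_posterior(**kw)
        if method == "variational":
            return self._fit_variational(**kw)
        if method == "svd":
            return self._fit_svd(**kw)
        raise ValueError(f"unknown method {method!r}")

    def _fit_posterior(self, inits=DEFAULT_INITS, sampler: SamplerConfig = None,
                       seed: int = 0) -> "KarplusPosteriorResults":
        cfg = sampler or SamplerConfig(n_replicas=self.n_replicas)
        traces, summaries = [], []
        for c, init in enumerate(np.atleast_2d(np.asarray(inits, float))):
            ccfg = replace(cfg, seed=seed + 65537 * c)
            tr, s = run_chain(self.ensemble, self.data, ccfg, self.likelihood,
                              init_thetas=init[None, :],
                              phi0=np.array([self.phi0]))
            traces.append(tr)
            summaries.append(s)
        return KarplusPosteriorResults(self, traces, summaries)

    def _fit_variational(self, inits=DEFAULT_INITS, schedule=None,
                         n_replicas: int = 4, eval_steps: int = 10_000,
                         seed: int = 0, maxfun: int = 40,
                         with_hessian: bool = False):
        opt = minimize_score(self.ensemble, self.data, inits, schedule,
                             self.likelihood, n_replicas=n_replicas,
                             eval_steps=eval_steps, seed=seed, maxfun=maxfun,
                             with_hessian=with_hessian)
        return KarplusVariationalResults(self, opt)

    def _fit_svd(self, epsilon: float = 1e-6, n_iter: int = 1000,
                 drop_frac: float = 0.10, seed: int = 0):
        theta, err, resid = svd_fit(self.ensemble, self.data, self.phi0,
                                    epsilon, n_iter, drop_frac, seed)
        return KarplusSVDResults(self, theta, err, resid)

    def score(self, theta, schedule: XiSchedule | None = None,
              sampler: SamplerConfig | None = None, seed: int = 0,
              **kw) -> ScoreResult:
        theta = (theta.as_array() if isinstance(theta, KarplusParams)
                 else np.asarray(theta, float))
        return compute_score(self.ensemble, self.data, theta, schedule,
                             sampler, self.likelihood, seed=seed, **kw)


# ----------------------------------------------------------------------
class _ResultsBase:
    def __init__(self, model: KarplusModel):
        self.model = model

    @property
    def karplus(self) -> KarplusParams:
        return KarplusParams.from_array(self.params, phi0=self.model.phi0)

    def predict(self, phi_deg=None) -> np.ndarray:
        """Couplings from the fitted coefficients; defaults to the
        population-averaged ensemble design points."""
        from .forward import karplus_predict
        from .svd import build_design_matrix
        if phi_deg is None:
            M = build_design_matrix(self.model.ensemble, self.model.phi0)
            return M @ self.params
        return karplus_predict(phi_deg, self.karplus)

    def plot_karplus(self, ax=None, label=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(-180.0, 180.0, 721)
        ax.plot(grid, self.predict(grid), label=label or "fit")
        ax.set_xlabel(r"$\phi$ (degrees)")
        ax.set_ylabel(r"$^3J$ (Hz)")
        return ax


class KarplusPosteriorResults(_ResultsBase):
    """Joint-posterior sampling results, averaged over chains."""

    def __init__(self, model, traces, summaries):
        super().__init__(model)
        self.traces = traces
        self.chain_means = np.array([s["theta_mean"][0] for s in summaries])
        self.params = self.chain_means.mean(axis=0)
        # within-chain posterior stdevs, averaged across chains
        self.bse = np.array([s["theta_std"][0] for s in summaries]).mean(axis=0)
        self.sigma_b = float(np.mean([s["sigma_b_mean"][0] for s in summaries]))
        self.sigma_b_map = float(np.mean([s["sigma_b_map"][0] for s in summaries]))
        self.phi_scale = float(np.mean([s["phi_mean"][0] for s in summaries]))
        self.phi_scale_map = float(np.mean([s["phi_map"][0] for s in summaries]))
        self.populations = np.mean([s["populations"] for s in summaries], axis=0)
        self._summaries = summaries

    def cov_params(self) -> np.ndarray:
        return np.mean([s["theta_cov"][0] for s in self._summaries], axis=0)

    @property
    def rhat(self) -> np.ndarray:
        """Gelman-Rubin statistic for (A, B, C) across chains."""
        if len(self.traces) < 2:
            raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")
        out = np.empty(3)
        for i in range(3):
            series = np.array([t.theta[:, 0, i] for t in self.traces])
            out[i] = gelman_rubin(series)
        return out

    def summary(self) -> str:
        names = ("A", "B", "C")
        lines = ["Karplus refinement (joint posterior, "
                 f"{len(self.traces)} chains, {self.traces[0].n_replicas} replicas)",
                 f"likelihood: {self.model.likelihood.model}", "-" * 56,
                 f"{'param':>6} {'mean':>10} {'post. sd':>10} {'R-hat':>8}"]
        rhat = self.rhat if len(self.traces) > 1 else [np.nan] * 3
        for i, nm in enumerate(names):
            lines.append(f"{nm:>6} {self.params[i]:>10.3f} "
                         f"{self.bse[i]:>10.3f} {rhat[i]:>8.3f}")
        lines.append("-" * 56)
        lines.append(f"sigma_B: mean {self.sigma_b:.3f} Hz, MAP "
                     f"{self.sigma_b_map:.3f} Hz; variance scale phi: mean "
                     f"{self.phi_scale:.2f}, MAP {self.phi_scale_map:.2f}")
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for i, nm in enumerate(("A", "B", "C")):
            for t in self.traces:
                ax.plot(t.theta[:, 0, i], lw=0.4)
            ax.set_xlabel("production sweep")
            ax.set_ylabel("coefficient (Hz)")
        return ax


class KarplusVariationalResults(_ResultsBase):
    """Score-minimisation results, aggregated over runs."""

    def __init__(self, model, opt: OptResult):
        super().__init__(model)
        self.opt = opt
        self.params = opt.theta_mean
        self.bse = opt.theta_std
        self.f_star = float(np.min(opt.f_star))

    def cov_params(self):
        return self.opt.covariance

    def summary(self) -> str:
        lines = [f"Karplus refinement (variational, {self.opt.n_runs} runs)",
                 "-" * 44,
                 f"{'param':>6} {'mean':>10} {'run sd':>10}"]
        for i, nm in enumerate(("A", "B", "C")):
            lines.append(f"{nm:>6} {self.params[i]:>10.3f} {self.bse[i]:>10.3f}")
        lines.append(f"best score f = {self.f_star:.3f} nats")
        return "\n".join(lines)


class KarplusSVDResults(_ResultsBase):
    """Ridge-stabilised population-weighted SVD fit."""

    def __init__(self, model, theta: KarplusParams, bse, resid):
        super().__init__(model)
        self.params = theta.as_array()
        self.bse = np.asarray(bse, float)
        self.resid = resid

    def summary(self) -> str:
        lines = ["Karplus fit (population-weighted SVD)", "-" * 44,
                 f"{'param':>6} {'value':>10} {'jackknife sd':>13}"]
        for i, nm in enumerate(("A", "B", "C")):
            lines.append(f"{nm:>6} {self.params[i]:>10.4f} {self.bse[i]:>13.4f}")
        lines.append(f"residual rms = {np.sqrt(np.mean(self.resid**2)):.4f} Hz")
        return "\n".join(lines)
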