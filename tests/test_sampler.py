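"""Replica MCMC sampler: proposals, detailed balance, diagnostics."""

import numpy as np
import pytest

from fmrefine import _kernels
from fmrefine.forward import KarplusParams, karplus_predict
from fmrefine.likelihood import (LikelihoodConfig, UncertaintyState, data_term)
from fmrefine.sampler import (ReplicaSystem, SamplerConfig, gelman_rubin,
                              posterior_summary, propose_theta, run_chain)
from fmrefine.toy import ToyEnsemble, make_toy_dataset


class TestProposeTheta:
    def test_identity_at_zero_rates(self):
        rng = np.random.default_rng(0)
        th = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            propose_theta(th, np.array([9.0, 9.0, 9.0]), 0.0, 0.0, rng), th)

    def test_deterministic_drift(self):
        rng = np.random.default_rng(0)
        out = propose_theta(np.zeros(3), np.array([1.0, 2.0, 3.0]), 0.1, 0.0,
                            rng)
        np.testing.assert_allclose(out, [-0.1, -0.2, -0.3], atol=1e-15)

    def test_noise_moment(self):
        rng = np.random.default_rng(1)
        draws = np.array([propose_theta(np.zeros(3), np.zeros(3), 0.0, 0.05,
                                        rng) for _ in range(30_000)])
        np.testing.assert_allclose(draws.std(axis=0), 0.05, rtol=0.02)


class TestKernelConsistency:
    def test_data_term_matches_reference(self):
        """Compiled kernel vs the pure-python energy, incl. two FM sets."""
        rng = np.random.default_rng(2)
        n_states, n_obs, N = 9, 10, 5
        G = rng.normal(5, 2, (n_states, n_obs))
        states = rng.integers(0, n_states, N)
        counts = np.bincount(states, minlength=n_states).astype(np.int64)
        cf = counts.astype(float)
        S1, S2 = cf @ G, cf @ (G ** 2)
        d = rng.normal(5, 2, n_obs)
        set_idx = np.array([0] * 6 + [1] * 4, dtype=np.int64)
        sigma_b = np.array([0.7, 1.3])
        phi_sc = np.array([2.3, 1.0])
        w = np.empty(n_obs)
        got = _kernels.data_term_kernel(S1, S2, d, set_idx, sigma_b, phi_sc,
                                        N, 1, 1, 1, w, True)
        expected = 0.0
        for k in range(2):
            sel = set_idx == k
            gk = G[states][:, sel]
            u = UncertaintyState(sigma_b=sigma_b[k],
                                 sigma_sem=gk.std(axis=0, ddof=0),
                                 phi_scale=phi_sc[k])
            expected += data_term(d[sel], gk.mean(axis=0), u, N,
                                  LikelihoodConfig(eq9_prefactor="half",
                                                   sem_convention="population"))
        assert got == pytest.approx(expected, abs=1e-9)


class TestRunChain:
    def test_bit_reproducible_under_seed(self, toy_small):
        ens, j = toy_small
        cfg = SamplerConfig(n_replicas=8, burn_steps=200, prod_steps=400,
                            seed=3)
        t1, _ = run_chain(ens, j, cfg, init_thetas=((4.0, 0.0, 3.0),))
        t2, _ = run_chain(ens, j, cfg, init_thetas=((4.0, 0.0, 3.0),))
        np.testing.assert_array_equal(t1.theta, t2.theta)
        np.testing.assert_array_equal(t1.energy, t2.energy)
        np.testing.assert_array_equal(t1.sigma_b, t2.sigma_b)

    def test_prior_recovery_at_xi_zero(self, toy_small):
        """With restraints off the states must follow the uniform prior."""
        from scipy import stats
        ens, j = toy_small
        cfg = SamplerConfig(n_replicas=8, burn_steps=500, prod_steps=10_000,
                            seed=4, sample_theta=False)
        tr, summ = run_chain(ens, j, cfg, init_thetas=((6.51, -1.76, 1.6),),
                             xi=0.0)
        occ = tr.occupancy
        expected = occ.sum() / ens.n_states
        chi2 = float(np.sum((occ - expected) ** 2 / expected))
        # occupancy draws are correlated across sweeps; scale dof generously
        assert chi2 / ens.n_states < 60

    def test_state_posterior_matches_exact_enumeration(self):
        """2-state, 1-observable, fixed nuisances: exhaustive Boltzmann check."""
        from itertools import product
        ens = ToyEnsemble(phi=[[0.0], [150.0]], populations=[0.5, 0.5])
        theta = KarplusParams(6.51, -1.76, 1.6)
        d = np.array([5.5])
        N = 3
        lcfg = LikelihoodConfig(phi_bounds=(1.0, 1.0 + 1e-12))
        G = karplus_predict(ens.phi, theta)

        logw = {}
        for states in product(range(2), repeat=N):
            g = G[list(states)].mean(axis=0)
            sem = G[list(states)].std(axis=0, ddof=0)
            u = UncertaintyState(0.8, sem, 1.0)
            logw[states] = -data_term(d, g, u, N, lcfg)
        z = np.logaddexp.reduce(list(logw.values()))
        # exact marginal occupancy of state 0
        p0 = sum(np.exp(lw - z) * states.count(0) / N
                 for states, lw in logw.items())

        cfg = SamplerConfig(n_replicas=N, burn_steps=1000, prod_steps=40_000,
                            seed=5, sample_theta=False, sample_sigma=False,
                            sample_phi=False, sigma_b_init=0.8, phi_init=1.0)
        tr, _ = run_chain(ens, d, cfg, lcfg, init_thetas=(theta.as_array(),))
        p0_hat = tr.occupancy[0] / tr.occupancy.sum()
        assert abs(p0_hat - p0) < 0.02  # total-variation criterion

    def test_nonfinite_initial_energy_raises(self, toy_small):
        ens, j = toy_small
        cfg = SamplerConfig(n_replicas=4, burn_steps=10, prod_steps=10)
        with pytest.raises(ValueError):
            run_chain(ens, j, cfg, init_thetas=((np.inf, 0.0, 0.0),))

    def test_gradient_burnin_reaches_basin_faster(self, toy_full):
        """Drifted burn-in must land near the basin well before plain MH."""
        ens, j_true = toy_full
        rng = np.random.default_rng(6)
        j = j_true + rng.normal(0, 0.3, j_true.size)
        results = {}
        for grad in (True, False):
            cfg = SamplerConfig(n_replicas=16, burn_steps=400, prod_steps=300,
                                seed=7, gradient_on_during_burn_only=grad,
                                lrate="auto" if grad else 0.0)
            tr, summ = run_chain(ens, j, cfg, init_thetas=((0.0, 0.0, 0.0),))
            results[grad] = abs(summ["theta_mean"][0][0] - 6.51)
        assert results[True] < results[False]


class TestGelmanRubin:
    def test_identical_chains_limit(self):
        x = np.random.default_rng(8).normal(size=1000)
        r = gelman_rubin(np.stack([x, x]))
        assert r == pytest.approx(np.sqrt(999 / 1000), abs=1e-12)

    def test_null_simulation_near_one(self):
        rng = np.random.default_rng(9)
        chains = rng.normal(size=(4, 10_000))
        assert 0.99 <= gelman_rubin(chains) <= 1.01

    def test_diverged_chains_flagged(self):
        rng = np.random.default_rng(10)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        assert gelman_rubin(chains) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestPosteriorSummary:
    def _trace(self, theta):
        from fmrefine.sampler import Trace
        n = theta.shape[0]
        return Trace(theta=theta, sigma_b=np.full((n, 1), 0.5),
                     phi_scale=np.ones((n, 1)), energy=np.zeros(n),
                     prior_term=np.zeros(n), data_term=np.zeros(n))

    def test_constant_trace(self):
        th = np.tile([[2.0, -1.0, 0.5]], (50, 1))[:, None, :]
        s = posterior_summary(self._trace(th))
        np.testing.assert_allclose(s["theta_std"], 0.0)
        np.testing.assert_allclose(s["theta_map"], [[2.0, -1.0, 0.5]],
                                   atol=1e-6)

    def test_normal_trace_moments(self):
        rng = np.random.default_rng(11)
        th = rng.normal(0, 1, size=(100_000, 1, 3))
        s = posterior_summary(self._trace(th))
        np.testing.assert_allclose(s["theta_mean"], 0.0, atol=0.02)
        np.testing.assert_allclose(s["theta_std"], 1.0, atol=0.01)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(self._trace(np.empty((0, 1, 3))))


class TestMultiSetSampling:
    def test_two_coupling_sets_refined_jointly(self):
        """Two observable blocks with different phases and coefficients."""
        from fmrefine.toy import sample_phi
        ens = sample_phi(n_states=40, n_obs=30, seed=12)
        set_idx = np.array([0] * 15 + [1] * 15)
        phi0 = np.array([0.0, 60.0])
        thA = KarplusParams(6.51, -1.76, 1.6, phi0=0.0)
        thB = KarplusParams(3.0, 0.5, 0.3, phi0=60.0)
        j = np.empty(30)
        j[:15] = ens.populations @ karplus_predict(ens.phi[:, :15], thA)
        j[15:] = ens.populations @ karplus_predict(ens.phi[:, 15:], thB)
        cfg = SamplerConfig(n_replicas=16, burn_steps=4000, prod_steps=8000,
                            seed=13)
        tr, summ = run_chain(ens, j, cfg,
                             init_thetas=((4.0, 0.0, 1.0), (4.0, 0.0, 1.0)),
                             set_idx=set_idx, phi0=phi0)
        means = summ["theta_mean"]
        # with 15 observables per set the posterior is broad; the check is
        # that the two blocks separate towards their own coefficients
        assert abs(means[0][0] - 6.51) < 1.0
        assert abs(means[1][0] - 3.0) < 1.0
        assert means[0][1] < -1.0 and abs(means[1][1] - 0.5) < 0.6
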