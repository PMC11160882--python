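"""Multistate reweighting (MBAR) free-energy estimator.

Given samples collected at K thermodynamic states with reduced energies
u_kn (state k evaluated on pooled sample n) and per-state sample counts N_k,
the dimensionless free energies f_k solve the self-consistent equations

    f_k = -ln sum_n exp(-u_kn) / sum_m N_m exp(f_m - u_mn).

They are obtained here by minimising the equivalent convex objective
kappa(f) = sum_n ln sum_k N_k exp(f_k - u_kn) - sum_k N_k f_k with an
analytic gradient (L-BFGS-B), which is robust even with poor overlap.
Statistical uncertainties are estimated by bootstrap resampling of the
per-state samples, with solves warm-started from the full-data solution.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = ["mbar_solve", "mbar_expectation", "overlap_adjacent", "MBARResult"]


class MBARResult:
    """Free energies (f_k, with f_0 = 0), log-weights and diagnostics."""

    def __init__(self, f_k, log_denom, u_kn, N_k, converged: bool):
        self.f_k = f_k
        self._log_denom = log_denom          # ln sum_m N_m exp(f_m - u_mn)
        self.u_kn = u_kn
        self.N_k = N_k
        self.converged = converged

    def weights(self) -> np.ndarray:
        """W[k, n] = exp(f_k - u_kn) / sum_m N_m exp(f_m - u_mn); rows sum to 1."""
        return np.exp(self.f_k[:, None] - self.u_kn - self._log_denom[None, :])


def _kappa(f, u_kn, N_k, logN):
    a = logN[:, None] + f[:, None] - u_kn       # (K, n)
    ls = logsumexp(a, axis=0)
    val = ls.sum() - float(N_k @ f)
    w = np.exp(a - ls[None, :])                  # N_k-weighted weights
    grad = w.sum(axis=1) - N_k
    return val, grad


def mbar_solve(u_kn, N_k, f_init=None, tol: float = 1e-10) -> MBARResult:
    """Solve for dimensionless free energies; ``f_k`` is gauge-fixed to f_0=0.

    Parameters
    ----------
    u_kn : (K, n_total) reduced energies of every pooled sample in every state.
    N_k : (K,) number of samples drawn from each state (may contain zeros).
    """
    u_kn = np.asarray(u_kn, dtype=float)
    N_k = np.asarray(N_k, dtype=float)
    K, n = u_kn.shape
    if N_k.shape != (K,) or N_k.sum() != n:
        raise ValueError("N_k must sum to the pooled sample count")
    # stabilise: subtract per-sample minimum (cancels in free-energy differences)
    shift = u_kn.min(axis=0)
    u = u_kn - shift[None, :]
    logN = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)
    f0 = np.zeros(K) if f_init is None else np.asarray(f_init, dtype=float).copy()
    res = minimize(_kappa, f0, args=(u, N_k, logN), jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": tol})
    f = res.x - res.x[0]
    a = logN[:, None] + f[:, None] - u
    log_denom = logsumexp(a, axis=0)
    # weights are gauge-invariant, so the shifted energies are kept throughout
    return MBARResult(f_k=f, log_denom=log_denom, u_kn=u, N_k=N_k,
                      converged=bool(res.success))


def mbar_expectation(result: MBARResult, observable, state: int) -> float:
    """Expectation of a pooled-sample observable in the given state's ensemble."""
    w = result.weights()[state]
    return float(w @ np.asarray(observable, dtype=float))


def overlap_adjacent(u_kn, N_k, f_k) -> np.ndarray:
    """Two-state overlap diagnostic for each adjacent pair of states.

    For states (k, k+1), builds the 2x2 MBAR overlap matrix from their own
    samples and returns its smallest eigenvalue; values near 0 signal
    vanishing phase-space overlap, values near 0.5 perfect overlap.
    """
    u_kn = np.asarray(u_kn, dtype=float)
    N_k = np.asarray(N_k, dtype=int)
    K = u_kn.shape[0]
    bounds = np.concatenate([[0], np.cumsum(N_k)])
    out = np.empty(K - 1)
    for k in range(K - 1):
        sel = np.r_[np.arange(bounds[k], bounds[k + 1]),
                    np.arange(bounds[k + 1], bounds[k + 2])]
        u2 = u_kn[np.ix_([k, k + 1], sel)]
        n2 = np.array([N_k[k], N_k[k + 1]], dtype=float)
        r = mbar_solve(u2, n2)
        W = r.weights()                      # rows sum to 1 over pooled samples
        O = (W * n2[:, None]) @ W.T          # (2, 2)
        out[k] = np.linalg.eigvalsh(O).min()
    return out
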