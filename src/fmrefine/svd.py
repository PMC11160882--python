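"""Population-weighted SVD fit of Karplus coefficients (comparison baseline).

The design matrix has one row per observable with population-averaged basis
functions (<cos^2(phi+phi0)>, <cos(phi+phi0)>, 1); the coefficients come
from the ridge-stabilised pseudo-inverse theta = V (Sigma + eps I)^-1 U^T J.
Uncertainties are estimated by repeatedly refitting on random subsets with a
fraction of the observables dropped.
"""

from __future__ import annotations

import numpy as np

from .forward import KarplusParams, karplus_basis

__all__ = ["build_design_matrix", "svd_solve", "jackknife_uncertainty", "svd_fit"]


def build_design_matrix(ens, phi0: float = 0.0, populations=None) -> np.ndarray:
    """Rows (<cos^2>, <cos>, 1), population-weighted over states."""
    p = ens.populations if populations is None else np.asarray(populations, float)
    if p.shape != (ens.n_states,):
        raise ValueError("populations shape mismatch")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("populations must be normalized")
    c2, c1 = karplus_basis(ens.phi, phi0)
    return np.column_stack([p @ c2, p @ c1, np.ones(ens.n_observables)])


def svd_solve(M, j_exp, epsilon: float = 1e-6, phi0: float = 0.0) -> KarplusParams:
    """theta = V (Sigma + eps I)^-1 U^T J_exp (ridge on all singular values)."""
    M = np.asarray(M, dtype=float)
    j_exp = np.asarray(j_exp, dtype=float)
    if M.ndim != 2 or M.shape[0] < 3:
        raise ValueError("need at least 3 observables to fit 3 coefficients")
    if M.shape[0] != j_exp.size:
        raise ValueError("design/data length mismatch")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if epsilon == 0.0 and np.any(s < 1e-12 * s.max()):
        raise np.linalg.LinAlgError("rank-deficient design with epsilon = 0")
    theta = Vt.T @ ((U.T @ j_exp) / (s + epsilon))
    return KarplusParams.from_array(theta, phi0=phi0)


def jackknife_uncertainty(ens, j_exp, phi0: float = 0.0, n_iter: int = 1000,
                          drop_frac: float = 0.10, seed: int = 0,
                          epsilon: float = 1e-6):
    """Stdev of (A, B, C) over refits each omitting ``drop_frac`` of the data."""
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if not 0.0 < drop_frac < 1.0:
        raise ValueError("drop_frac must be in (0, 1)")
    M = build_design_matrix(ens, phi0)
    j_exp = np.asarray(j_exp, dtype=float)
    n = M.shape[0]
    keep = n - int(round(drop_frac * n))
    if keep < 3:
        raise ValueError("subset smaller than 3 observables")
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_iter, 3))
    for i in range(n_iter):
        idx = rng.choice(n, size=keep, replace=False)
        coefs[i] = svd_solve(M[idx], j_exp[idx], epsilon).as_array()
    return coefs.std(axis=0, ddof=1)


def svd_fit(ens, j_exp, phi0: float = 0.0, epsilon: float = 1e-6,
            n_iter: int = 1000, drop_frac: float = 0.10, seed: int = 0):
    """Convenience: fitted KarplusParams, jackknife stdevs and residuals."""
    M = build_design_matrix(ens, phi0)
    theta = svd_solve(M, j_exp, epsilon, phi0=phi0)
    err = jackknife_uncertainty(ens, j_exp, phi0, n_iter, drop_frac, seed,
                                epsilon)
    resid = np.asarray(j_exp, float) - M @ theta.as_array()
    return theta, err, resid
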