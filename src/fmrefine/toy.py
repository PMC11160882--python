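"""Synthetic toy system for benchmarking forward-model refinement.

Backbone dihedral angles are drawn from a three-mode Gaussian mixture that
mimics the phi-angle distribution of protein secondary structure (beta sheet,
right-handed helix, left-handed helix).  Each conformational state carries one
phi angle per observable, and synthetic ensemble-averaged J-couplings are
computed from a known "true" Karplus relation, optionally corrupted with
random (Gaussian) and systematic (positive-shift outlier) error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import KarplusParams, karplus_predict

__all__ = [
    "ModeSpec",
    "ToyEnsemble",
    "NoiseSpec",
    "TOY_MODES",
    "TRUE_KARPLUS",
    "sample_phi",
    "synthetic_observables",
    "inject_noise",
    "perturb_prior",
    "make_toy_dataset",
]


def wrap_angle(phi_deg):
    """Wrap angles (degrees) into (-180, 180]."""
    phi = np.asarray(phi_deg, dtype=float)
    wrapped = -np.mod(-phi + 180.0, 360.0) + 180.0
    return wrapped


@dataclass(frozen=True)
class ModeSpec:
    """One Gaussian mode of the phi-angle mixture (degrees)."""

    mu: float
    sigma: float
    weight: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"mode sigma must be positive, got {self.sigma}")
        if self.weight < 0:
            raise ValueError(f"mode weight must be non-negative, got {self.weight}")


#: Secondary-structure mixture: beta sheet, right-handed helix, left-handed helix.
TOY_MODES = (
    ModeSpec(mu=-110.0, sigma=20.0, weight=0.35),
    ModeSpec(mu=-60.0, sigma=10.0, weight=0.50),
    ModeSpec(mu=60.0, sigma=5.0, weight=0.15),
)

#: Ground-truth Karplus coefficients of the toy system (Hz).
TRUE_KARPLUS = KarplusParams(A=6.51, B=-1.76, C=1.6)


@dataclass
class ToyEnsemble:
    """Conformational ensemble: per-state, per-observable phi angles plus populations.

    ``phi`` is indexed ``[state, observable]`` in degrees, wrapped to
    (-180, 180].  ``populations`` are the prior state populations p(X).
    """

    phi: np.ndarray
    populations: np.ndarray
    state_ids: list = field(default_factory=list)
    observable_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.populations = np.asarray(self.populations, dtype=float)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi angles must be finite")
        if self.populations.shape != (self.phi.shape[0],):
            raise ValueError(
                f"populations shape {self.populations.shape} does not match "
                f"{self.phi.shape[0]} states"
            )
        if np.any(self.populations < 0):
            raise ValueError("populations must be non-negative")
        if abs(self.populations.sum() - 1.0) > 1e-6:
            raise ValueError("populations must sum to 1")
        self.phi = wrap_angle(self.phi)
        if not self.state_ids:
            self.state_ids = [f"s{i}" for i in range(self.n_states)]
        if not self.observable_ids:
            self.observable_ids = [f"j{i}" for i in range(self.n_observables)]

    @property
    def n_states(self) -> int:
        return self.phi.shape[0]

    @property
    def n_observables(self) -> int:
        return self.phi.shape[1]


@dataclass(frozen=True)
class NoiseSpec:
    """Random plus systematic noise applied to synthetic couplings.

    ``sigma_data`` is the stdev of i.i.d. Gaussian noise (Hz).  A fraction
    ``bad_fraction`` of the observables (chosen uniformly without replacement)
    additionally receives a uniform systematic shift in
    ``[shift_lo, shift_hi]`` Hz, emulating outlier measurements.
    """

    sigma_data: float = 0.0
    bad_fraction: float = 0.0
    shift_lo: float = 2.0
    shift_hi: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_data < 0:
            raise ValueError("sigma_data must be >= 0")
        if not 0.0 <= self.bad_fraction <= 0.2:
            raise ValueError("bad_fraction must be in [0, 0.2]")
        if self.shift_lo > self.shift_hi:
            raise ValueError("shift_lo must be <= shift_hi")


def _validate_modes(modes) -> tuple:
    modes = tuple(modes)
    if not modes:
        raise ValueError("need at least one mixture mode")
    wsum = sum(m.weight for m in modes)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"mode weights must sum to 1, got {wsum}")
    return modes


def sample_phi(modes=TOY_MODES, n_states: int = 100, n_obs: int = 60,
               seed: int = 0, populations=None,
               column_structure: bool = True,
               state_jitter: float = 5.0) -> ToyEnsemble:
    """Draw a toy ensemble of phi angles from the secondary-structure mixture.

    With ``column_structure=True`` (default) each observable behaves like a
    residue of a real protein: it keeps a characteristic angle across
    conformational states.  The residue centre angle is drawn from the
    secondary-structure mixture, and the conformational states scatter
    around it with a small thermal jitter (``state_jitter`` degrees).  The
    per-observable ensemble averages then spread over the full Karplus
    curve, keeping the coefficient fit well conditioned, and prior-ensemble
    perturbations of a few degrees are a meaningful degradation.

    With ``column_structure=False`` every (state, observable) entry is an
    independent mixture draw; the per-observable averages then all collapse
    onto the global mixture mean and the coefficients are only weakly
    identified (useful for degenerate-design studies).

    Populations default to uniform 1/n_states.
    """
    modes = _validate_modes(modes)
    if n_states < 1 or n_obs < 1:
        raise ValueError("n_states and n_obs must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([m.weight for m in modes])
    mus = np.array([m.mu for m in modes])
    sigmas = np.array([m.sigma for m in modes])
    if column_structure:
        comp = rng.choice(len(modes), size=n_obs, p=weights)
        centers = rng.normal(mus[comp], sigmas[comp])   # (n_obs,)
        phi = rng.normal(centers, state_jitter, size=(n_states, n_obs))
    else:
        comp = rng.choice(len(modes), size=(n_states, n_obs), p=weights)
        phi = rng.normal(mus[comp], sigmas[comp])
    if populations is None:
        populations = np.full(n_states, 1.0 / n_states)
    return ToyEnsemble(phi=wrap_angle(phi), populations=populations)


def synthetic_observables(ens: ToyEnsemble, theta: KarplusParams) -> np.ndarray:
    """Noise-free ensemble-averaged couplings sum_X p(X) J(phi[X, j]; theta)."""
    J = karplus_predict(ens.phi, theta)  # (n_states, n_obs)
    return ens.populations @ J


def inject_noise(J, spec: NoiseSpec) -> np.ndarray:
    """Apply Gaussian noise plus systematic positive shifts to a coupling vector."""
    J = np.asarray(J, dtype=float)
    rng = np.random.default_rng(spec.seed)
    out = J + rng.normal(0.0, spec.sigma_data, size=J.shape) if spec.sigma_data > 0 \
        else J.copy()
    n_bad = int(round(spec.bad_fraction * J.size))
    if n_bad > 0:
        idx = rng.choice(J.size, size=n_bad, replace=False)
        out[idx] += rng.uniform(spec.shift_lo, spec.shift_hi, size=n_bad)
    return out


def perturb_prior(ens: ToyEnsemble, sigma_prior: float, seed: int = 0,
                  mode: str = "entry") -> ToyEnsemble:
    """Degrade the prior ensemble with Gaussian angle errors (populations kept).

    ``mode="entry"`` jitters every (state, observable) angle independently;
    ``mode="column"`` draws one error per observable and shifts its whole
    column, i.e. displaces the residue's characteristic angle.  Column
    errors move the per-observable ensemble averages by the full
    sigma_prior and so model a structurally wrong prior; independent entry
    errors mostly average out and model extra thermal blur.
    """
    if sigma_prior < 0:
        raise ValueError("sigma_prior must be >= 0")
    if mode not in ("entry", "column"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    if sigma_prior == 0:
        return replace(ens, phi=ens.phi.copy(), populations=ens.populations.copy())
    rng = np.random.default_rng(seed)
    if mode == "column":
        shift = rng.normal(0.0, sigma_prior, size=ens.n_observables)
        phi = wrap_angle(ens.phi + shift[None, :])
    else:
        phi = wrap_angle(ens.phi + rng.normal(0.0, sigma_prior, size=ens.phi.shape))
    return ToyEnsemble(phi=phi, populations=ens.populations.copy(),
                       state_ids=list(ens.state_ids),
                       observable_ids=list(ens.observable_ids))


def make_toy_dataset(n_states: int = 100, n_obs: int = 60, seed: int = 0,
                     noise: NoiseSpec | None = None,
                     theta: KarplusParams = TRUE_KARPLUS):
    """Convenience: ensemble, true couplings and (optionally noisy) data.

    Returns ``(ensemble, j_true, j_exp)`` where ``j_true`` are the noiseless
    population-averaged couplings under the true Karplus coefficients and
    ``j_exp`` the noise-corrupted synthetic experimental values.
    """
    ens = sample_phi(n_states=n_states, n_obs=n_obs, seed=seed)
    j_true = synthetic_observables(ens, theta)
    j_exp = inject_noise(j_true, noise) if noise is not None else j_true.copy()
    return ens, j_true, j_exp
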