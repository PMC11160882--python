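# Methods

## The model

`fmrefine` reconciles a simulated conformational ensemble with
ensemble-averaged NMR scalar couplings while refining the empirical
forward model that predicts the observables.  The forward model is the
Karplus relation

    3J(phi) = A cos^2(phi + phi0) + B cos(phi + phi0) + C,

mapping a backbone dihedral phi (degrees) to a three-bond J-coupling (Hz);
phi0 is a fixed, coupling-type-specific phase.  The data enter through a
replica-averaged likelihood: N replicas each occupy one conformational
state X_r, and the prediction compared with the experimental value d_j is
the replica mean g_j = (1/N) sum_r J(phi[X_r, j]).  In the large-N limit
this is a maximum-entropy reweighting of the prior populations — no
regularisation weight has to be chosen.

The effective uncertainty per observable combines an experimental
(Bayesian) scale sigma_B, sampled under a truncated Jeffreys prior, with
the finite-sampling error sigma_SEM of the replica mean:
sigma0^2 = sigma_B^2 + sigma_SEM^2.  Two likelihoods are available:

* **Gaussian** — all observables share sigma0.
* **Good–Bad** — a two-component mixture: "good" observables have
  variance sigma0^2, "bad" (outlier) ones an inflated variance
  (phi*sigma0)^2 with variance scale phi >= 1; the unknown bad fraction is
  marginalised analytically, giving per observable the likelihood
  [N(g|d, sigma0^2) + N(g|d, phi^2 sigma0^2)] / 2 with both components
  normalised.  phi is sampled with a Jeffreys prior p(phi) ~ 1/phi.
  At phi = 1 the Good–Bad energy equals the Gaussian one exactly.

Two refinement routes are implemented and shown to agree on the toy
system:

1. **Joint posterior sampling** — (A, B, C) are sampled together with the
   replica states and nuisances by MCMC.  A sweep proposes one uniform
   state re-assignment per replica, a log-space walk on sigma_B, a
   reflected walk on phi, and a Gaussian move on theta.  During burn-in
   the theta proposal is drifted along the negative energy gradient
   (theta_trial = theta - lrate * grad u + eta * z); the drift is switched
   off for production so proposals are symmetric and detailed balance
   holds (verified against exact enumeration on a discrete system,
   total-variation < 0.02).  Several chains from disperse starts are
   averaged and monitored with the Gelman-Rubin statistic.

2. **Variational score minimisation** — the model quality score
   f(theta) = -ln Z(theta)/Z0 is the free energy of switching the
   experimental restraints on.  A family of posteriors raises the
   likelihood to a power xi in [0, 1]; chains are run at a schedule of xi
   values and the end-to-end free energy is estimated by multistate
   reweighting (MBAR), implemented in-package as an L-BFGS-B minimisation
   of the convex MBAR objective and validated against exact enumeration.
   The theta-gradient of the score is the posterior average of the energy
   gradient at xi = 1, and bounded L-BFGS-B (bounds A in [0, 15],
   B in [-10, 10], C in [-5, 10] Hz) minimises f.  The score is extensive
   in the replica count (asymptotically; the measured doubling ratio is
   ~1.9 at 16 -> 32 replicas), hence the reduced score f/N_r is reported.

A small neural forward model (2 -> 200 -> 1, GELU activations,
LeCun-normal initialisation, numpy with hand-written reverse-mode
gradients) replaces the Karplus form in the NN-training path: the dihedral
enters through the unit-circle embedding (cos phi, sin phi), making
predictions periodic and continuous at +-180 degrees.  Training minimises
the restraint energy with Adam (2000 epochs, learning rate 1e-3 by
default); each epoch re-samples the nuisance posterior at the current
predictions, and re-sampling sigma is the implicit regulariser — freezing
it measurably degrades the final fit.

## Numerical and design choices

* **Angles** are degrees at every API boundary, radians internally,
  wrapped to (-180, 180].
* **Mixture prefactor.**  Marginalising the unknown bad fraction with
  normalised Gaussian components gives equal 1/2 prefactors on both
  mixture components; this is the default.  An alternative convention
  with a 1/(2 phi) prefactor on the broad component is available
  (`eq9_prefactor="half_phi"`) but adds an extra ln(phi) penalty per
  outlier that prevents the heavy tail from ever being engaged — with it
  the outlier-absorbing mode is never favoured and robustness to
  systematic shifts is lost.
* **SEM convention.**  The default finite-sampling error is the
  population standard deviation of the per-replica predictions
  (`sem_convention="population"`).  The sample-stdev/sqrt(N) variant is
  available (and is what `replica_average` exposes for the 1/sqrt(N)
  scaling property), but as the sigma0 floor it admits a degenerate
  mixture spike: replica reweighting can tune a few residuals to ~0 and
  sigma0 then chases them with near-unbounded likelihood, leaving chains
  trapped in disagreeing modes.  The population floor (the full replica
  spread) suppresses the spike and yields stable, reproducible chains.
* **sigma_B support** defaults to [0.05, 10] Hz — typical NMR frequency
  uncertainties are 0.1-1.0 Hz, and a positive physical floor removes the
  remaining degenerate-spike mass.  Bounded supports also make the xi = 0
  reference evidence finite, which the score requires.
* **phi support** is [1, 20].  phi is initialised high (10) and held
  fixed during burn-in: single-coordinate Metropolis moves cannot cross
  the joint (sigma_B, phi) barrier between the "absorb outliers in a
  broad Gaussian" mode and the "flag outliers with the heavy tail" mode,
  so burn-in starts with the heavy tail active; on clean data phi relaxes
  towards 1 during production.  Burn-in is discarded, so the phi
  posterior is unaffected.
* **Heaviside convention** H(0) = 0, so at sigma_B -> 0 both mixture
  components remain active (no measure-zero discontinuity).
* **Gradients.**  The theta-gradient of the energy weights each residual
  by the mixture responsibilities over the inverse variances; it treats
  sigma_SEM as fixed with respect to theta.  The neglected SEM-derivative
  term vanishes for zero replica spread (where the gradient matches a
  deterministic quadrature oracle to ~1.5%) and is irrelevant for its two
  uses: burn-in proposal drift (any drift is admissible on discarded
  samples) and the L-BFGS-B search direction.
* **xi schedule.**  Default 11 values.  `optimize_xi_schedule` spaces
  them equidistantly in estimated thermodynamic length: short pilot
  chains give the per-xi standard deviation of du/dxi (= the data term),
  the cumulative trapezoid of that density is inverted by monotone
  interpolation, iterating at most a few rounds until the per-interval
  lengths agree within 10%.  A flat density degenerates to uniform
  spacing.  This is a deliberately simple equal-length spacer, not a
  reimplementation of more elaborate schedule optimisers.
* **MBAR.**  Solved by L-BFGS-B on the convex objective with analytic
  gradient (tolerance 1e-10); statistical error by bootstrap over
  per-state sample resampling (32 resamples, warm-started), with samples
  thinned before estimation to reduce autocorrelation.  Adjacent-state
  overlap (smallest eigenvalue of the pairwise 2x2 overlap matrix) is
  reported as a diagnostic.
* **Stochastic objective.**  Score evaluations inside one variational run
  reuse the same chain seeds (common random numbers), making the
  objective deterministic in theta so quasi-Newton line searches are
  reliable.  The Hessian at the optimum is estimated by central finite
  differences (step 0.05 Hz, repeats averaged); its inverse is the
  parameter covariance, reported only when positive definite.
* **Sampler defaults** are calibrated to ~10-50% acceptance on the toy
  system: theta step eta = 0.01 Hz, log-sigma step 0.05, phi step 0.1
  (0.3 in the benchmark studies), auto learning rate 1e-4 capped so the
  initial drift step never exceeds 0.3 Hz.  Tie acceptance at
  delta-u = 0 accepts.
* **Reproducibility.**  All randomness is pre-generated from one
  Generator per chain and consumed inside the compiled (numba) sweep
  kernel, so traces are bit-identical under a fixed seed.  The running
  sums behind the energy are checked against a full recomputation at the
  end of every chain.

## The synthetic system

The toy system emulates backbone dihedrals of a protein.  Angle
distribution: a three-mode Gaussian mixture — beta sheet
(mu = -110, sigma = 20, w = 0.35), right-handed helix (-60, 10, 0.5),
left-handed helix (60, 5, 0.15), all in degrees.  Each observable
(residue) draws one characteristic centre angle from the mixture, and the
conformational states scatter around it with a 5-degree thermal jitter;
the marginal over all angles follows the mixture, while the
per-observable ensemble averages spread over the full Karplus curve so
the three coefficients are well identified (an i.i.d.-per-entry variant,
`column_structure=False`, collapses all ensemble averages onto the global
mixture mean and leaves the coefficients identified only to a few Hz).
The 5-degree jitter also makes prior perturbations of up to 4 degrees — 
the range scanned by the prior-quality study — a meaningful degradation.
True coefficients: A = 6.51, B = -1.76, C = 1.6 Hz.  Default size: 100
states x 60 observables with uniform populations (the NN study uses 5
states x 60 observables).  Noise: i.i.d. Gaussian of magnitude sigma_data
plus systematic +2..+4 Hz shifts on up to 20% of the observables (the
count per trial is drawn uniformly in the sweep, fixed when a single
value is configured).

What the generator does *not* emulate: correlated noise across
observables, non-uniform prior populations, multiple coupling types per
observable set (supported by the machinery, exercised only in unit
tests), and any real structural physics beyond the angle marginals.
Passing benchmarks therefore demonstrate the estimators' correctness and
calibration under the stated error model, not transferability to any
particular protein dataset.

## Benchmark protocols and problem sizes

The studies in `fmrefine.studies` (also driven by
`scripts/acceptance.py`) use reduced problem sizes chosen to keep a full
pass to minutes on one core while leaving the estimates' means unchanged:

* robustness sweep: 10 repeats per noise level (5 levels), three chains
  of 3k burn + 8k production sweeps per trial, 32 replicas;
* prior-quality study: 100 perturbed priors (10 levels x 10
  realisations), 11 xi values, 800 + 2400 sweeps per chain; one fixed
  dataset whose noise magnitude is drawn from N(0.68, 0.24) Hz; the
  regression is on level-averaged scores (single-realisation scatter —
  which observables got shifted and by how much — is irreducible and
  caps a raw-point regression near R^2 ~ 0.4);
* convergence and single-trial studies: full 10k burn + 50k production,
  32 replicas, three chains;
* variational study: 4 replicas, 10k production sweeps per objective
  evaluation split across the schedule, at most 25 evaluations per run,
  three runs.

## Known limitations

* At high injected noise (sigma_data ~ 1 Hz) the mean coupling RMSE of
  the refined coefficients exceeds the ideal-estimator floor
  sigma*sqrt(3/60) by about 1.3-1.7x; the floor itself implies a mean
  RMSE over the swept levels of ~0.12 Hz, so sub-0.1 averages are not
  attainable under this protocol (see the per-level numbers the
  acceptance script prints).
* The population-SEM floor softens the likelihood at very low noise,
  shrinking |A| slightly (downweighting of high-leverage observables).
* The NN forward model extrapolates smoothly but inaccurately over the
  angle arc the mixture never visits (+90..+200 degrees); curve-recovery
  statements are therefore made on the data-supported range.
* MBAR error bars come from an i.i.d. bootstrap of thinned samples and
  can be optimistic when chains are short.
* Multi-set (K > 1) refinement shares the replica states across coupling
  types, as the joint posterior dictates; per-set independent replica
  systems are not offered.
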