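# Methods

## The fractal rate model

A compartment model moves drug amounts A between well-mixed pools at
first-order rates. `fractalpk` replaces any chosen micro-rate constant k
with an instantaneous rate coefficient

    k(t) = θ / max(t − t_ref, ε)^h ,   0 ≤ h ≤ 1,

where t_ref is the fractal-clock origin (by default the time of the first
dose), θ (1/h) is the coefficient at elapsed time 1, and h is the
heterogeneity exponent. Time is measured in hours and the quantity raised
to the power h is treated as dimensionless, so θ keeps units of 1/h for
every h. h = 0 reduces the expression *exactly* to the classical constant
(the implementation short-circuits the power, so classical and h = 0
profiles are bit-identical).

Supported structures: 1 or 2 compartments; absorption by first-order
depot, by a transit chain, or none (bolus into the central compartment);
dose fractionation over parallel fast (first-order) and slow (transit)
pathways; and an optional per-dose rule that resets the fractal clock to
the dose time and empties the depot/in-transit amounts before the new dose
is added (used for multiple-dose regimens where each administration
re-creates the depot). Parameters follow the clearance parameterization:
Ke = CL/V1, Kcp = Q/V1, Kpc = Q/V2.

The transit chain uses the closed-form gamma-flow input
ktr·(ktr·t)^n·e^(−ktr·t)/n! with Stirling's approximation
n! ≈ √(2π)·n^(n+1/2)·e^(−n) (n ≥ 1; defaults n = 3, ktr = 1/h — chain
length and rate are user parameters). An explicit "in-transit" balance
state integrates the negative of that inflow so total mass is accountable
at all times; note Stirling's approximation undershoots n!
(n!/Stirling(n) ≈ 1.027 at n = 3), so the *absorbed* total is a few
percent above the nominal transit fraction — an intrinsic property of the
published input function, not an integration error. Mass balance
(depot + transits + central + peripheral + eliminated = administered dose)
holds to < 1e-6 relative in tests for every supported structure.

### The ε regularization

θ/t^h is unbounded at t = t_ref. For h < 1 its integral is finite, so the
profile is well defined; ε (default 1e-6 h, configurable) merely keeps the
right-hand side finite for the solver. Halving ε perturbs the cumulative
hazard by θ·h/(1−h)·ε^(1−h)·(1−2^(h−1)): ~1e-7 at h = 0.1 but ~1e-4 at
h = 0.5 and O(1) as h → 1, where the early profile is genuinely
ε-dominated (the h = 1 boundary is allowed but its near-dose behavior
should not be over-interpreted). Tests assert ε-insensitivity at the level
this scaling supports rather than a single blanket tolerance.

## Simulation

Integration restarts at every dose event (doses are applied discretely,
post-dose state reported at the event time). Two backends produce
identical results within tolerance:

- a compiled adaptive Dormand–Prince RK45 (rtol 1e-8, atol 1e-10 defaults)
  for non-transit structures — the workhorse for estimation and
  simulation-based diagnostics;
- scipy `solve_ivp` (LSODA by default) for transit chains and any other
  structure.

Accuracy is pinned by two independent closed forms: the Bateman function
for classical first-order absorption (max relative error ~5e-10 on the
0–400 h grid) and the stretched-exponential
A(t) = A₀·exp(−θ(t^(1−h) − t₀^(1−h))/(1−h)) for single-pool fractal decay
(~3e-9). Runs are deterministic: identical inputs give bit-identical
tables.

The sweep design runs three scenarios (1-compartment; 2-compartment with
peripheral volume 100 L or 1 L against a 10 L central volume; Q = 3 L/h),
Ka/CL pairings (0.033, 0.3), (0.1, 0.1), (0.3, 0.033) — absorption slower
than, equal to and faster than clearance — one fractal target at a time,
h from 0 to 1 in steps of 0.05 (21 values), a 100 mcg extravascular dose
at t = 0, and an output grid of 0–400 h at 0.5 h (801 points, dense enough
for peak detection). Regime features are read off the raw grid:
local maxima with prominence ≥ 1% of the profile maximum (suppresses
solver ripple while keeping visually meaningful double peaks), the time of
the global maximum, and the central fraction remaining at the end of the
window ("trapping").

## Population model and estimation

Per subject i, structural parameters are θᵢ = θ_pop·exp(ηᵢ) with
ηᵢ ~ N(0, Ω), Ω diagonal; residual error on the concentration scale is
y = f + √(σ_add² + σ_prop²·f²)·ε with ε ~ N(0, 1). The heterogeneity
exponent enters the fixed effects as `h_<rate>`, is estimated on the logit
scale (hence always inside [0, 1]) and carries no IIV; positive
parameters are estimated on the log scale.

The marginal likelihood is approximated by Laplace with interaction:

1. inner problem — for each subject, minimize over η
   g(η) = Σⱼ [log 2πv_j(η) + (y_j − f_j(η))²/v_j(η)]
        + q·log 2π + log|Ω| + ηᵀΩ⁻¹η,
   with the residual variance v evaluated at the *individual* prediction
   (interaction). A damped Newton iteration uses the analytic gradient and
   the Gauss–Newton (Fisher) Hessian
   H = Ω⁻¹ + Σⱼ [JⱼJⱼᵀ/v_j + ½·(∂v_j)(∂v_j)ᵀ/v_j²], with J = ∂f/∂η from
   central finite differences (step 1e-4); convergence at max|∇g| < 1e-8.
2. subject contribution — −2·log Lᵢ ≈ g(η̂) − q·log 2π + log|H(η̂)|. For a
   model linear in η with additive error this algebra is exact.
3. outer problem — OFV(θ, Ω, σ) = Σᵢ −2 log Lᵢ is minimized by L-BFGS-B
   on the transformed parameters (finite-difference gradients, relative
   ftol 1e-8 ≈ 1e-6 on the OFV; Nelder–Mead available as an option).
   Subject modes are warm-started between outer iterations. The reported
   OFV is the full −2 log marginal likelihood including 2π constants.

The Laplace OFV was cross-checked against brute-force Gauss–Kronrod
quadrature of the marginal likelihood on a one-random-effect toy model:
agreement to 4e-5 at near-degenerate Ω, and to ~0.15 at 30% IIV with a
single observation per subject — the expected Laplace bias for very
sparse designs; it cancels almost entirely in OFV *differences* between
nested models on the same data, which is how OFV is used here.

`robustify` confirms a minimum the way pharmacometric workflows do:
re-optimization from starts jittered ±20% on the log scale and — when an
Ω diagonal has collapsed toward zero — from a start with those entries
reset to 0.09 (saddle-point reset). The lowest OFV wins; counts of
restarts and improvements are reported.

## Synthetic populations

`generate_population` draws η per subject, integrates the true model over
the design's dosing regimen and sampling times, adds residual noise, and
emits NONMEM-dialect records (doses EVID=1 with AMT, observations EVID=0
with DV; CMT 1-based with compartment 1 = depot for extravascular models;
'.' marks missing DV). The same seed always reproduces the same dataset;
no global RNG state is used anywhere. Negative simulated observations are
kept by default (they are what the additive-error likelihood expects);
truncation at 0 is available per design.

The generator emulates the *designs* of sparse-to-rich clinical PK
studies (single or multiple extravascular doses, 8–44 subjects, sampling
windows from 48 h to thousands of hours) but not their pathologies: no
dropout, no BLQ censoring, no covariates, no model misspecification
beyond what a test injects deliberately. Passing recovery and diagnostic
suites therefore demonstrates the estimator and diagnostics are correct
and well calibrated under the stated model — not that the model fits any
particular clinical dataset.

The recovery study fixture is a 2-compartment fractal-absorption
population: Ka = 0.3/h with h = 0.3, CL = 0.5 L/h, V1 = 10 L, Q = 1 L/h,
V2 = 20 L, 30% CV IIV on Ka and CL, 15% proportional error, 100 mcg
extravascular dose, 12 samples over 72 h. Intercompartmental parameters
(Q, V2) are held at their known values so the scaled 10-subject problem
stays well identified; the checked quantities are the recovered fixed
effects, the estimated h, the OFV gain of the fractal term over the h = 0
fit, and the type-I rate of a spurious h on classically generated data.

## Diagnostics

- `criteria`: AIC = OFV + 2k, AICc = AIC + 2k(k+1)/(n−k−1), exact
  arithmetic; AICc is flagged undefined for n ≤ k+1. k counts every
  estimated quantity (fixed effects + Ω diagonal + σ terms).
- `lrt_significant`: threshold = χ²₁₋α quantile at the added degrees of
  freedom (3.84 / 5.99 at α = 0.05 for 1 / 2 df); significant when the
  OFV decrease reaches it.
- `gof`: PRED from η = 0, IPRED from the empirical Bayes modes,
  IWRES = (DV − IPRED)/sd(IPRED); CWRES from the FOCE linearization about
  the EBEs — E = f(η̂) − Jη̂, Cov = JΩJᵀ + diag(v(η̂)), residuals
  decorrelated by the Cholesky factor of Cov. Note that with proportional
  error the interaction term shifts the conditional mode off zero by
  O(Ω) even for noise-free data, so "perfect-model CWRES ≈ 0" holds
  exactly only as Ω → 0.
- `pcvpc`: equal-count time bins (default 8, empty bins merged left);
  each observed and simulated value scaled by
  (bin median PRED)/(individual PRED); observed 5/50/95th percentiles per
  bin against the 2.5–97.5% span of the same percentiles over n_sim
  simulated datasets (default 500).
- `npde`: n_sim replicate datasets (default 1000 — higher than the VPC
  default for rank resolution); per subject, observed and simulated
  vectors decorrelated with the simulation mean and Cholesky factor of the
  simulation covariance (ridge-regularized if singular); the prediction
  discrepancy is pde = (#sims below)/n_sim with uniform jitter on ties,
  clamped to [1/(2·n_sim), 1 − 1/(2·n_sim)] before the Φ⁻¹ transform.
  Summaries: mean (t-test), variance (two-sided χ² test against 1),
  Shapiro–Wilk normality and excess kurtosis.

## Numerical choices and limitations

- Estimation-path solver: the compiled RK45 at rtol 1e-8 / atol 1e-10;
  fast and general paths agree on the OFV to ~1e-4 on the test fixtures.
- Outer finite-difference step 1e-4 on the transformed scale; inner
  Newton line search halves up to 25 times; non-finite proposals (|η| >
  20, solver divergence) are rejected via an infinite objective rather
  than aborting the fit.
- Scaled suite sizes: 10 subjects × 5 replicates for recovery, 200
  simulations for VPC/NPDE in the test suite (the library defaults remain
  500/1000).
- Laplace-with-interaction is an approximation: absolute OFVs need not
  match other software's values; comparisons should stay within one
  implementation.
- TMDD structures, covariate submodels and physiological (PBPK) fractal
  models are out of scope.
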