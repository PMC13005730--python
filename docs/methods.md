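# Methods

## Model

The joint model couples a longitudinal generalized linear mixed model
(GLMM) with cause-specific proportional hazards through shared random
effects `b_i ~ N(0, Σ_θ)`:

* longitudinal sub-model: `g(E[Y_ij | b_i]) = γᵀx_i(t_ij) + b_iᵀz(t_ij)`.
  Supported families are Gaussian (identity link, residual variance σ²)
  and Poisson (log link). The fixed design is `[1, t, baseline covariates]`;
  the random design is `[1]` (intercept) or `[1, t]` (intercept+slope).
* survival sub-model: `λ_k(t|b_i) = λ_0k(t) exp(β_k m_i(t) + α_kᵀx2_i)`
  for competing causes `k = 1..K`, where `m_i(t)` is the current
  model-implied biomarker value. With `K = 1` this is a Cox-type model
  with a parametric baseline. Baselines are piecewise constant on
  `(ν_{q−1}, ν_q]` with the last piece extended beyond `ν_Q` (new data
  can outlive the fitted knots). The interval is closed on the right:
  an event at exactly `ν_q` belongs to piece `q`.

Each subject's marginal likelihood integrates the survival density (and,
for sub-cohort members, the longitudinal density) over `b`. Censored
subjects contribute only the all-cause survival term; subjects outside
the NCC sub-cohort contribute survival-only terms with the longitudinal
density replaced by 1 (their biomarkers are missing at random given the
observed survival data, which is exactly how NCC selection operates).

## Estimators

* **fJM-NCC** maximizes the full-cohort likelihood. Covariance is the
  inverse empirical Fisher information (outer products of per-subject
  scores).
* **wJM-NCC** maximizes `Σ_i w_i log L_i` over the sub-cohort with
  inclusion weights `w_i = (1 − Π_{l∈S_i}(1 − m_l/n_l))⁻¹` (cases:
  `w_i = 1`), where `S_i` ranges over the cases whose matched risk set
  contained subject `i`; the implementation recomputes eligibility
  exactly from the survival table. Covariance is the sandwich
  `I⁻¹ΣI⁻¹` with `I` the negative Hessian of the weighted log-likelihood
  (central differences of the analytic gradient) and `Σ` the outer
  product of per-subject weighted scores. The naive `I⁻¹` ("Fisher")
  variant is retained for comparison; it systematically understates
  uncertainty when weights are large (small control-to-case ratio m).
* **Comparators**: naive JM (identical machinery applied to the
  sub-cohort as if it were a cohort; biased because the sub-cohort
  event rate is distorted to ≈ 1/(m+1)) and conditional logistic
  regression on matched sets via the exact conditional likelihood with
  Newton iterations (mean biomarker value per member, since CLR cannot
  carry time-varying covariates).

Wald tests and 95% CIs come from the natural-scale delta method; the
unconstrained optimization vector uses log transforms for σ² and ξ and a
log-Cholesky factor for Σ_θ, so every iterate is a valid model.
Multiplicity is handled by Bonferroni (per-cause species counts) or
Benjamini–Hochberg (FDR control in the multi-feature screen; the
procedure behind the reported FDR was not specified upstream, and BH is
the standard choice).

## Numerics

* **Quadrature.** For the Gaussian/identity family the longitudinal
  density times the Gaussian prior factorizes exactly through the
  closed-form posterior of `b` given the measurements, so Gauss–Hermite
  nodes are centered and scaled per subject at that posterior and only
  the slowly varying survival factor is integrated numerically
  (15 nodes per dimension by default). This matters: a prior-centered
  rule at 15 nodes mis-evaluates a subject with ~17 measurements by up
  to 0.25 log-likelihood units, enough to bias variance components,
  while the posterior-centered rule is accurate to ~1e−9. For the
  Poisson family the rule stays prior-centered (no closed-form
  posterior); an adaptive mode (numerically located posterior mode and
  curvature) is available on the per-subject entry point. Node counts
  are configurable everywhere.
* **Cumulative hazards.** With the identity link the trajectory is
  linear in time, so each baseline segment integrates in closed form
  (`∫ ξ e^{a+cs} ds`); the `c → 0` degeneracy is handled by clamping
  `|βc|` away from zero at 1e−8, costing O(1e−8) relative error. Under
  the log link each segment uses 7-point Gauss–Legendre.
* **Optimization.** L-BFGS-B on the unconstrained vector with analytic
  gradients (posterior-weighted score identities) for Gaussian/identity
  models and central differences otherwise. Initialization: γ, σ², Σ_θ
  from a longitudinal-only decomposition (OLS plus within/between
  variance split), β = 0, baselines from weighted occurrence/exposure
  rates per interval, α from a cause-specific exponential-rate Poisson
  regression. Convergence requires the optimizer's relative-improvement
  test plus a scaled gradient below 1e−4; non-convergence is flagged,
  never silently accepted. Log-densities are floored at −745 before
  exponentiation inside the quadrature; variance parameters are bounded
  within ±12 on the log scale and baseline log-hazards within [−20, 5]
  to keep rare degenerate escapes (σ² → 0) from derailing replicate
  studies. A numba-compiled kernel evaluates the Gaussian/identity
  likelihood and scores; the vectorized numpy evaluator is kept as the
  reference implementation and fallback, and the test suite enforces
  agreement to machine precision.

## Simulator and its calibration

The simulator draws `b_i`, inverts each cause-specific cumulative hazard
against an independent unit exponential (closed form per segment for the
identity link, bracketed root-finding otherwise), applies uniform
random censoring and then administrative censoring at the event time of
the `n_cases_target`-th observed case, and reveals grid-spaced biomarker
measurements truncated at each subject's observed time (per-subject
noise streams, so revealing a subset matches revealing everyone).

True parameter defaults are calibrated, not copied: trajectory
`γ = (0, 0.5)`, random-intercept variance 1, σ² = 1, constant baselines
`ξ = (0.0161, 0.0080)` — the first cause dominant, consistent with the
reported precision ordering of the two association estimates — effects
`α = (0.3, 0.2)` on a Bernoulli(0.5) covariate, censoring `U(0, 4)`. At
N = 8000 this yields ≈ 435 observed cases against the 400-case target
(within the ±10% calibration band). Desk-scale runs use N = 2000 with a
100-case target and censoring `U(0, 5)` so the target is reliably
reachable; replicate studies exclude (and count) the rare draws or fits
that fail.

The multi-feature generator replaces an external microbiome synthesizer
with independent Gaussian log-abundance trajectories (one random
intercept per feature per subject); a configured fraction of features
enters both cause-specific hazards with fixed coefficients. Because
every signal feature contributes, the aggregate acts on the hazard as an
unobservable frailty plus a time trend; single-feature refits are
therefore mildly misspecified — as they are for real multi-taxon data.
The shipped desk-scale screen (N = 800, 90 cases, m = 1, 50 features,
10% signals, measurement grid 0.5, trajectory slope 0.1) keeps that
aggregate small, and fits use a 3-piece baseline so the trend is
absorbed by `λ_0k` rather than by spurious associations. Non-converged
per-feature fits are treated as missing (never discoveries).

## What the desk-scale studies do and do not show

Passing replicate studies at N = 2000/100 cases demonstrate: unbiased
association estimates for fJM-NCC and wJM-NCC under null and
alternative, calibrated sandwich coverage, strictly lower naive-Fisher
coverage, nominal type-I error, attenuation of the naive JM shrinking
with m, and BH-FDR control with the expected power ordering
(benchmark ≥ fJM-NCC ≥ wJM-NCC). They do not reproduce full-scale
magnitudes that depend on N = 8000/400-case information: in particular
the naive-Fisher undercoverage is milder here (≈ 0.92 vs the reported
0.857 for β₂) because weight-driven variance inflation grows with the
full design's risk-set structure, and empirical FDR sits below the
nominal 0.05 because discoveries are only moderately frequent at this
power. Real-data features not emulated: irregular visit schedules,
missing visits, measurement batch effects, compositional zero-inflated
abundances, and matching on more than one exact factor.

## Known limitations

* Random-effect dimension is capped at 2 (intercept, intercept+slope).
* Cause-specific hazards only; no sub-distribution (cumulative
  incidence) modeling.
* Exact-matching NCC only; no counter-matching or stratified designs.
* The Poisson path has no analytic scores and is slower; it is intended
  for modest sub-cohort sizes.
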