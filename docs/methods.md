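# Methods

This note documents the models, estimators, numerical choices, and known
limits of `methapop`.  Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not reproduce.

## Structural pharmacokinetic models

Both candidate models are linear with first-order oral absorption and are
evaluated in closed form at multiple-dose steady state.

* **Two-compartment**: micro-constants (CL/F, V/F, k12, k21, ka).  The
  disposition exponents α ≥ β are the roots of
  λ² − (k10+k12+k21)λ + k10·k21 with k10 = CL/F ÷ V/F, computed stably as
  α = (s + √(s²−4p))/2, β = p/α.  The single-dose concentration is the
  standard three-exponential partial-fraction expansion; the coefficients
  sum to zero so C(0) = 0 (no intravenous component).
* **One-compartment**: k12 = k21 = 0, two-exponential solution in (k10, ka).
  For this model the package defines α = β = k10, so the terminal half-life
  ln2/β remains meaningful; the two-exponential observable equals the
  two-compartment solution in the k12 → 0 limit.

**Steady state.**  Each exponential term e^(−λt) is accumulated over past
doses by its geometric factor 1/(1 − e^(−λτ)).  Query times are reduced
modulo τ, making the pre-dose trough addressable at t = 0 and t = τ
interchangeably; the profile is exactly τ-periodic.  Predictions are linear
in dose.  Units are fixed package-wide: mg, L, h, with a single mg/L →
ng/ml factor of 1000 applied at output.

**Degenerate exponents.**  If ka (or ke0, below) falls within 1e-8·α of a
disposition exponent, it is perturbed by 1e-6 relative instead of switching
to the repeated-root solution — the coincidence is a measure-zero case and
a second code path is not worth its surface.

**Oracles.**  The closed forms are verified against (i) truncated
superposition of ≥ 40·t½β/τ single doses and (ii) direct ODE integration
of the depot/central/peripheral(/effect) system to periodic steady state,
both to ≤ 1e-5 relative error over randomized parameter sets.

## Population PK estimation (MAP-EM)

Individual log-parameters carry normal random effects about log-scale
population means (log-normal inter-subject variability, diagonal Ω);
residual error is proportional with variance σ² and prediction-based
weights 1/ŷ² (prediction-based rather than observation-based weighting
avoids biasing the weights with measurement noise).

The estimator alternates:

* **E-step** — per-subject MAP maximization of the log posterior.  The
  subject problems are separable, so they are stacked into a single
  L-BFGS-B run with batched (vectorized-across-subjects) model evaluation
  and batched central-difference gradients; warm-started between
  iterations.
* **M-step** — population means as the mean of the MAP estimates; IIV
  variances as the mean of squared deviations plus the posterior-curvature
  correction diag(H⁻¹) (clipped to [0, ω] per component), H being the
  per-subject Hessian of the negative log posterior; σ² from the weighted
  squared residuals divided by an effective degrees of freedom
  N − Σᵢ Σₖ (1 − hᵢₖ/ωₖ) − (#shared), which discounts the parameters the
  subjects absorbed (without this correction σ² is biased low and the IIV
  spuriously inflates).

Convergence: the largest relative parameter change must stay below 1e-4 for
5 consecutive iterations; the cap is 500 iterations and a fit that reaches
it is flagged non-converged rather than raising.  The marginal
log-likelihood for AIC is the Laplace approximation at the MAP estimates;
AIC = −2·loglik + 2·P with P = (all fixed effects) + (estimated IIV
variances) + 1 for σ².  Model selection takes the lowest-AIC converged fit,
ties broken toward fewer parameters; the pipeline falls back to the
lowest-AIC fit with a warning when no candidate reaches the formal
convergence streak.

**Which parameters carry random effects.**  By default CL/F, V/F and ka
are random; k12 and k21 are fixed effects shared across subjects and
updated in the M-step by pooled likelihood-only maximization.  A 6–7-point
steady-state design cannot inform five random effects per subject: with all
five random, the approximate marginal likelihood is flat along a ridge and
the EM drifts (we measured V/F sliding ~25% along that ridge with the k21
variance inflating severalfold, at essentially constant likelihood).  A
random effect whose variance collapses to the floor (1e-8) is handed over
to the pooled fixed-effect update, since the mean-of-MAPs update can no
longer move it.  `random_effects` is configurable, including all
parameters, for users who want the full specification.

**Initial values** default to literature-derived presets (CL/F 8 L/h,
V/F 130 L, k12 0.5 h⁻¹, k21 0.25 h⁻¹, ka 0.4 h⁻¹), IIV variance 0.2, σ²
0.04.  BLQ observations (< 5 ng/ml, the assay's quantification limit) are
excluded from fitting and counted in the log; a subject with no usable
observation is dropped with a warning.  Any stochastic fallback
(multi-start after optimizer failure) is seeded (default 20110601), so fits
are deterministic and independent of subject order.

## Pharmacodynamics

The effect site follows dCe/dt = ke0(Cp − Ce); its steady-state closed form
adds one ke0-exponential per plasma term plus the ke0 accumulation factor.
SOWS is modelled as E = E0·[1 − Emax·Ceⁿ/(Ceⁿ + EC50ⁿ)] — the inhibitory
sigmoid-Emax form: monotone non-increasing in Ce, bounded in
[E0(1−Emax), E0].  The printed rendering of this equation is ambiguous
about grouping; this standard inhibitory form is the one consistent with
the stated variable definitions.

**Hysteresis.**  `hysteresis_loop_area` is a pure shoelace signed area
(positive = counter-clockwise).  For an inhibitory response the raw
(Cp, SOWS) trajectory runs clockwise; the pharmacological convention plots
the *drug effect*, i.e. withdrawal suppression E0 − E, for which the lagged
loop is counter-clockwise — `suppression_loop_area` applies that
convention.  On the default profile the area is positive for every finite
ke0 and collapses as ke0 → ∞; it also vanishes as ke0 → 0 (the effect-site
profile flattens to the interval average), so the area is not monotone from
arbitrarily small ke0 — it peaks near ke0 ≈ 0.5 h⁻¹ for this profile.

**Two-stage population fit.**  Stage one fits each subject's (E0, Emax,
log EC50) by bounded least squares (`scipy.optimize.least_squares`, trf)
against that subject's SOWS series, with Ce built from the subject's (MAP
or true) PK parameters; residuals are unweighted (additive error on a
bounded integer score).  ke0 (default 0.5 h⁻¹) and n (default 1) are fixed
unless enabled — six or seven observations cannot support five free PD
parameters.  Multi-start over a coarse (Emax, EC50) grid guards against
local minima.  A subject whose EC50 lands on a search bound
([10, 5000] ng/ml) or whose Emax → 1 is flagged *non-identified*: its data
do not constrain the concentration–effect relationship, and it is excluded
from the stage-two EC50/Emax summary (E0 is summarized over all successful
fits).  Stage two reports mean, SD, t-based 95% CI, min, max and
fold-change (max/min), with Emax displayed ×100.

## Cohort statistics

Summary blocks follow the mean / SD / 95% CI / min / max / fold-change
layout with SD on n−1 denominators and t-distribution CIs.  Note the CI
columns printed in the original summary tables are not consistent with
n = 60 under any standard formula; the package computes standard t-based
CIs and does not attempt to match those cells.  Fold change is undefined
(reported missing) when the minimum is ≤ 0.  Dose–trough association uses
Pearson correlation with its two-sided t-test; paired comparisons use the
paired t-test or the two-sided Wilcoxon signed-rank test (all-zero
differences return p = 1 by convention); multi-group comparisons use
one-way ANOVA.  The SOWS time profile tests each post-dose time against
each subject's own pre-dose score, unadjusted by default (a Holm option
exists); subjects without a pre-dose record are excluded with a warning.

## Synthetic cohorts

`generate_cohort` emulates the study design: 60 subjects on once-daily oral
methadone; doses from a truncated normal (mean 58, SD 34, resampled into
[5, 170] mg); sampling at {0, 1, 2, 4, 6, 10, 24} h (the protocol drew a
pre-dose sample plus 4–5 more over 24 h; exact per-patient times are
unpublished, so this grid is a declared, configurable convention).  PK and
PD parameters are per-subject log-normal, moment-matched to the published
population means and SDs (σ² = ln(1+(sd/mean)²), μ = ln mean − σ²/2); Emax
draws are truncated to (0, 1).  E0 defaults (mean 25, SD 8) are generator
conventions chosen to keep scores inside [0, 64] with visible suppression —
they are config values, not claims about the study.  Concentrations carry
mean-one multiplicative log-normal noise (CV 0.15); values below 5 ng/ml
are flagged BLQ.  SOWS totals are the model effect plus additive Gaussian
noise (SD 3), rounded and clamped to [0, 64]; item-level simulation is
omitted since only totals are analyzed.  One RNG stream per cohort,
consumed in subject-major order, makes every dataset bit-reproducible from
its seed.

What the generator does *not* emulate: covariates (weight, CYP genotype,
co-medication), dropout and missingness, assay drift, dose titration over
time, within-subject occasion variability, and any tolerance dynamics in
the PD response.  Passing recovery tests therefore demonstrate estimator
correctness under the assumed data-generating model, not robustness to
real-world violations of it.

## Problem sizes and identifiability limits

The recovery experiments run at the study scale (60 subjects, 6–7 samples
each); the AIC model-recovery experiment uses 10 replicate 60-subject
cohorts, and the pipeline smoke tests use 8–16 subjects.

Three limits of this *design* (not of the code) surface repeatedly and are
worth stating plainly:

* **V/F** is identified only by the shape of the within-interval
  fluctuation (the interval mean depends on CL/F alone).  Its sampling SE
  on the log scale is ~0.15–0.25 under this design: pointwise evaluations
  of the exact (adaptive Gauss–Hermite) marginal likelihood show cohorts on
  which the data genuinely prefer a V/F 20–25% below the generating value.
  Recovery within ±15% therefore depends on the seed.
* **Model discrimination** between one- and two-compartment disposition is
  weak at steady state, where accumulation flattens the distribution
  phase: AIC prefers the true two-compartment model in about 8 of 10
  replicate cohorts, typically by only a few AIC units.
* **(Emax, EC50)** are near-unidentifiable from SOWS under these
  conditions: the within-subject effect swing is ~0.5 points against
  observation noise of SD 3, and the between-subject dose–response signal
  is confounded by the multiplicative E0 variability (CV ~32%).  Both the
  per-subject two-stage fits and an exact-marginal mixed-model
  cross-check (E0 random, Emax/EC50 fixed effects, closed-form Gaussian
  marginal) land on a likelihood ridge — the latter frequently at the
  Emax = 1 boundary with *better* likelihood than the generating values.
  The two-stage summaries are reported honestly with their non-identified
  subjects flagged and excluded; their population means should be read
  with these limits in mind.

The population fit is also initial-value dependent along the flat V/F–ka
ridge: starting far from the literature preset can settle ~15% away in
V/F.  The shipped preset is the package's declared anchor, mirroring the
original analysis's use of literature-derived initial estimates.
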