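# Methods

This note records the scientific and numerical choices behind the
package: the score family and its assumptions, the derivation machinery,
the diagnostic statistics, and what the synthetic cohorts do and do not
emulate.

## The score family

The Diabetes Fibrosis Index belongs to a *factored-quadratic* family in
five variables,

    S = θ_age·Age + a_p·Plt·(1 − c_p·Plt) + a_s·AST·(1 − c_s·AST)
      + θ_alt·ALT + a_b·BMI·(1 − c_b·BMI),

linear in age and ALT and quadratic-through-the-origin in platelets,
AST, and BMI. The factored form a·X·(1 − c·X), rather than the expanded
pair (a·X, −a·c·X²), is kept throughout because it is directly
interpretable: |a| is the slope at the origin and 1/(2c) the value of X
at which the term's contribution is stationary (a maximum when a > 0, a
minimum when a < 0). For the published coefficients the stationary
points are Plt ≈ 314.5 ×10⁹/L, AST ≈ 137.0 IU/L, and BMI ≈ 34.1 kg/m² —
clinically sensible saturation points. Curvatures are constrained
non-negative; a = 0 or c = 0 recovers a plain linear term.

Classification convention: a patient is at-risk when score ≥ cut-off,
everywhere (the published cut-off is 715 for the DFI and 1.3 for FIB-4).
Scores are dimensionless and never rounded before classification.

FIB-4 itself is not printed alongside the index; the standard published
definition (Age × AST)/(Plt[10⁹/L] × √ALT) is used and treated as an
external dependency of the method.

## Genetic-algorithm derivation

Coefficients are fitted by maximizing the empirical AUROC for advanced
fibrosis (stage ≥ F3). AUROC is invariant under monotone transforms of
the score and piecewise constant in the coefficients, so gradient
methods do not apply directly; a real-coded genetic algorithm searches
the 8-gene vector (θ_age, a_p, c_p, a_s, c_s, θ_alt, a_b, c_b).

Defaults (all exposed in `GAConfig`):

| parameter | default | rationale |
|---|---|---|
| population | 200 | standard for an 8-dimensional real-coded GA |
| generations | 250 | fitness plateaus well before this on n ≈ 10³ cohorts |
| tournament size | 3 | mild selection pressure; ties go to the earlier index for determinism |
| crossover | BLX-0.5, rate 0.9 | plain arithmetic blend is variance-contracting and caused premature convergence; the extended blend keeps exploring |
| mutation | per-gene prob 0.3, Gaussian, s.d. 0.1×range annealed geometrically to 0.001×range | ranking fitness needs coarse moves early and fine moves late |
| elitism | 2 | preserves the incumbent; makes the best-fitness trajectory monotone |
| restarts | 4 | see below |
| bounds | amplitudes within ±10× the published magnitudes; curvatures in [0, 0.1] | covers every plausible rescaling of the index |

Three design points deserve explanation:

* **Orientation correction.** A score and its negation carry identical
  ranking information (AUC and 1 − AUC), so fitness is
  max(AUC, 1 − AUC). Each generation, reversed-orientation members are
  also flipped to positive orientation before breeding: mating
  mirror-image parents would otherwise breed toward the useless zero
  score. A result whose raw AUC was below 0.5 is returned negated when
  the bounds admit it, with a flag recording the reversal.
* **Log-uniform initialization.** Amplitudes and curvatures span orders
  of magnitude, and the quantity a curvature controls — the stationary
  point 1/(2c) — is uniform on a log scale, not a linear one. Sampling
  gene magnitudes log-uniformly over three decades below each bound
  covers the family's behavioral range; uniform sampling concentrates
  almost all mass on strongly saturated terms and reliably missed the
  basin of the generating model in recovery experiments (train AUROC
  stalled ≈ 0.03–0.08 below it).
* **Restarts.** The AUROC landscape has strong local optima (a
  one-variable-dominated score is a typical trap). Independent runs find
  the global basin about 75% of the time on the recovery benchmark, so
  four restarts (seeded via a spawned seed sequence, best result kept)
  reduce the miss probability to well under 1%.

Recovery benchmark: 2000 synthetic patients labelled from the published
index through a logistic link (scale 80 around the cut-off, giving a
generating AUROC ≈ 0.8), 70/30 stratified split. The refitted model's
held-out AUROC lands within ~0.005 of the generating model's across
seeds. With everything fixed, the whole fit is bit-reproducible and runs
in ~35 s on one core.

## Diagnostic statistics

* **AUC** is the tie-corrected Mann–Whitney estimator (ties count one
  half), computed from midranks; it equals the trapezoidal area under
  the empirical ROC, which stores one operating point per distinct score
  plus sentinels at ±∞.
* **Correlated AUCs** (two scores on the same patients) are compared
  with DeLong's structural-components test: placement values per
  positive and per negative patient, covariance of the paired AUC
  estimators, two-sided normal p-value. A paired patient bootstrap is
  available behind a flag as an alternative variance estimator; on small
  fixed instances the two agree within 15%, and under a permutation null
  the test's type-I error is nominal (≈ 0.05).
* **Cut-off policies**: largest cut-off with sensitivity ≥ target;
  Youden's J with ties broken toward higher sensitivity; largest cut-off
  with NPV ≥ target at a supplied prevalence. Returned cut-offs sit at
  the midpoint of the score gap below the qualifying operating point, so
  classification at the returned value reproduces that operating point
  exactly (on separable data Youden returns the separating-gap
  midpoint). Infeasible targets raise an error carrying the attainable
  (cut-off, sensitivity, specificity) frontier.
* **Age-stratified reports** use the published band layout (≤25, 26–35,
  …, 66–75) plus a catch-all band for ages over 75, which the published
  table omits; bands are configurable. Band AUROC is computed from
  band-local scores and labels, not from the global ROC restricted to
  the band. PPV/NPV are reported absent (not 0/0) when the corresponding
  predicted class is empty.
* **Risk factors**: one jointly adjusted logistic model by default
  (per-covariate crude fits on request), per-unit odds ratios without
  standardization, Wald 95% CIs exp(β ± 1.96·SE), two-sided Wald
  p-values. The maximum-likelihood fit is statsmodels' IRLS with
  convergence tolerance 1e-8; perfect separation and rank deficiency are
  detected and reported with the offending covariate where identifiable.
* **Interaction structure** between index variables is summarized two
  ways, because the estimator behind published interaction surfaces is
  unspecified: an assumption-free empirical prevalence over
  quantile-edged 2-D bins (primary), and a smoothed companion from a
  logistic fit with main effects, squares, and the product term. The
  product term is tested by a 1-df likelihood-ratio test; variables are
  standardized internally for numerical stability only (the LR statistic
  is invariant to affine rescaling).

## Synthetic cohorts

No patient-level data accompany the published index; only group-level
baseline tables are available. The simulator is therefore built to match
*exactly those published statistics* and nothing more:

* Four strata: T2DM × advanced fibrosis, with P(T2DM) = 517/1503,
  P(≥F3 | T2DM) = 0.30, P(≥F3 | non-T2DM) = 0.132. Stage within class
  follows the printed splits F3:F4 = 112:43 and (F0/1):F2 = 228:134,
  with the lumped F0/1 divided evenly between F0 and F1.
* Continuous variables use truncated normals whose underlying location
  and scale are solved numerically (two-moment matching) so that the
  *truncated* distribution has the published mean and SD. Naive
  truncation at physiologic lower bounds would bias skewed labs — ALT
  with mean 78 and SD 59 truncated at zero shifts the realized mean by
  about +11 IU/L, many standard errors at n = 5000. A lognormal family
  is available per variable.
* Per-class laboratory moments are published only for the T2DM strata;
  both non-T2DM strata share the non-T2DM marginals. Consequences: in
  non-T2DM patients the index has no association with stage by
  construction, and cohort-level AUCs on synthetic data reflect only
  between-group mean differences — they are *not* expected to reproduce
  published cohort AUCs (0.771/0.735), which depend on the real joint
  distribution. Those values are reproduced as pipeline structure, not
  as numbers.
* Correlations between variables are not published. A Gaussian copula
  applies artifact defaults (AST–ALT 0.7, AST–age 0.1, platelets–age
  −0.2, all else 0); the copula leaves marginal moments untouched, and
  the defaults are fully configurable.
* The diabetes label is consistent by construction: non-T2DM strata draw
  glucose and HbA1c from moment-matched distributions truncated below
  the diagnostic thresholds (126 mg/dL fasting glucose; HbA1c 6.5%), and
  any T2DM record that fails all three diagnostic criteria has its
  medication flag set. HbA1c moments and medication rates are not
  published; clinically typical values are used (T2DM 7.3 ± 1.3%, 70%
  on medication; non-T2DM 5.5 ± 0.4%, none). One published
  inconsistency is resolved in favor of the total-population table: the
  T2DM cholesterol mean is taken as 118.12 mg/dL (the subgroup table
  prints 188.12 for the same quantity).
* Weekly alcohol is a truncated exponential (scale 30 g) kept strictly
  below the MASLD limits (210 g men, 140 g women), so every generated
  record passes the eligibility filter.

`validate_generation` compares realized per-stratum moments against the
specification, standardized by the sampling SE, flagging |z| > 4. At
n = 5000 realized means sit within 3 SE of every published value and the
class prevalences within ±0.02.

What passing tests on synthetic cohorts shows: the pipeline's
statistics, estimators, and derivation machinery behave correctly under
realistic marginal structure. What it does not show: performance of the
index on real patients, whose joint covariate–stage structure the
simulator deliberately does not invent.

## Problem sizes and tolerances

Tests and the acceptance script use: n = 5000 for simulator fidelity
(3-SE bands), n = 2000 with a 70/30 split for GA recovery (0.02 AUROC
band), 2000 replicates for type-I calibration ([0.03, 0.07] at
α = 0.05), 10⁵ bootstrap replicates for the DeLong-variance cross-check
(15% relative band on a 12-patient instance), and 500 random instances
of size ≤ 30 for the AUC-vs-pair-counting identity (exact up to float
round-off). Logistic fits are checked against the closed-form 2×2 odds
ratio and SE to 1e-6 relative error. Moment matching solves to residuals
below 1e-6·max(1, SD); the copula correlation matrix is required PSD and
gets a 1e-12 diagonal jitter before Cholesky.

## Known limitations

* The GA optimizes in-sample AUROC only; no sensitivity-constrained or
  multi-objective fitness, and no gradient/convex surrogate.
* No confidence intervals on per-band metrics, and no calibration
  analysis of predicted risks.
* Odds-ratio tables assume per-unit scaling; covariates measured on very
  different scales should be interpreted accordingly.
* The simulator matches first and second moments and stated prevalences
  only; higher moments, within-class correlations with stage in
  non-T2DM patients, and measurement error processes are not modelled.
* Records with missing optional labs are carried but never imputed;
  operations that need a missing field fail loudly with the record ids.
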