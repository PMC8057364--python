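# Methods

This note documents the models behind `catex`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, the
numerical conventions, and the package's known limitations.

## The capacity-to-pay CHE statistic

The statistic follows the WHO "health expenditure distribution" methodology.
All computation happens on **annualized, single-currency** data; the
pipeline refuses mixed-period input (the money convention travels with every
dataset precisely so that a second ×12 annualization is an error, not a
silent corruption).

**Equivalence scale.** Household size enters as `size**beta` with
`beta = 0.56`, the standard value for this methodology, exposed as
configuration.  `beta = 1` recovers the raw head count; a single-person
household is always exactly one equivalent adult.

**Poverty line.** The line is the mean per-equivalent-adult *food*
expenditure of the reference households — those whose food budget share lies
inside an inclusive percentile window of the sample food-share distribution,
default the 45th–55th percentiles.  Percentiles use the empirical
(nearest-rank) definition: the p-th percentile is the value at rank
`ceil(p/100 · n)`.  This definition is fixed and documented because
interpolating definitions differ across libraries and would make the
reference window — and hence every downstream number — platform-dependent.
With a single household, the window degenerates to that household.
Aggregation is the unweighted mean (the emulated survey is self-weighting);
a weight column is honoured when supplied.  Households with zero total
expenditure are excluded from the window with a warning; an empty window or
an all-zero-food window raises instead of guessing.

**Capacity to pay and the substitution rule.** `PC_h = THE_h − SE_h` with
`SE_h = line · size^beta`.  Where a household spends below its estimated
subsistence (`THE_h < SE_h`), the line is replaced by the household's own
food spending, so `PC_h = THE_h − food_h ≥ 0`.  Because ingestion rejects
rows with `food > total`, capacity to pay is positive after substitution
whenever the household spends anything beyond food.

**Flags and incidence.** `CHE_h = 1` iff `OOP_h / PC_h ≥ z` — the boundary
is closed (a household at exactly 30% is catastrophic).  The degenerate case
`PC_h = 0` flags 1 exactly when `OOP_h > 0` (any positive spending against
zero capacity is catastrophic at every threshold) and logs a warning.
Incidence is formed in exact rational arithmetic before the final float.
The 95% interval is the Wilson score interval, chosen over the Wald interval
for its behaviour near 0% and 100%.  The threshold sweep
(10/20/30/40%) reuses one decomposition pass; flags are pointwise monotone
in the threshold, so incidence is non-increasing across the sweep.

Scale invariance: multiplying every money column by any `c > 0` rescales
line, SE, PC and OOP together and leaves every flag and incidence unchanged;
this is tested to 1e-12 on the ratios.

## Determinants stage

The response is the CHE flag at a chosen threshold (default 0.30; 0.40
available, and fits at 0.10/0.20 may legitimately fail — see "Degenerate
fits" below).  Money covariates enter in 1000-peso units so a coefficient
reads "change per additional 1000 MXN".

**Logit.** Maximum likelihood via statsmodels, with Wald standard errors and
CIs, McFadden pseudo-R², and the likelihood-ratio chi-square against the
intercept-only model.  Marginal effects default to **average marginal
effects** (the dominant modern convention; effects-at-means are available
behind a flag): for a continuous covariate the sample mean of
`b_j p_i (1 − p_i)`, for a binary covariate the contrast in mean predicted
probability between the two counterfactual states, both with delta-method
standard errors.  The tests verify each AME against a central finite
difference of the mean predicted probability to 1e-6.

**Linear probability model.** OLS of the flag on the same covariates with
HC1 robust standard errors — an LPM is intrinsically heteroskedastic, so
classical errors would be wrong by construction.  Its slopes *are* its
marginal effects.  The LPM is a faithful summary only while predicted
probabilities stay mid-range (roughly 20–80% prevalence); the package keeps
both models side by side (`compare_models`) so sign agreement and magnitude
differences are visible rather than assumed.

**Stepwise selection.** Classic bidirectional entry–removal on Wald
p-values: add the best candidate below `p_enter` (default 0.05), then drop
the worst included covariate above `p_remove` (default 0.10; admissibility
requires `p_enter ≤ p_remove`).  Ties break by column order, making the
procedure deterministic; every step is written to an audit log; revisiting a
model aborts with a diagnostic rather than cycling.  Stepwise inference is
used here as a variable-screening device, as in the analysis it mirrors —
post-selection p-values are not corrected.

**Degenerate fits.** The logit's `converged` flag is honest: non-convergence,
non-finite estimates, or a non-vanishing gradient are reported, and perfect
or quasi-separation raises a `SeparationError` naming the separating
covariate when one exists.  At low thresholds nearly every household is
flagged and the likelihood has no interior maximum; the package surfaces
this instead of returning numbers.

**Subgroup tests.** Pearson chi-square on the flag × group table without
continuity correction, `df = (r−1)(c−1)`; empty groups are dropped with a
warning.  Descriptive tables use Welch's t for continuous variables and the
same chi-square for categorical ones.

## Synthetic household survey

The generator stands in for survey microdata that are not publicly
deposited.  Its defaults describe a plausible population of 387 households
caring for a psychiatric outpatient in a middle-income urban setting:

- **Income**: lognormal, `(mu, sigma) = (8.668, 0.592)` in log-MXN/month,
  giving mean ≈ US$338/month and sd ≈ US$219 at 20.48 MXN/USD.
- **Consumption**: non-health consumption is `0.85 · income` plus additive
  Gaussian noise (sd 1500 MXN/month ≈ US$73), floored at 20% of income.
  The additive-homoskedastic form is deliberate: multiplicative noise makes
  the latent scale of the CHE indicator income-dependent and distorts every
  marginal-effect comparison.
- **Engel food share**: `0.40 − 0.07 · z(log income) + N(0, 0.06)`, clipped
  to [0.05, 0.90] — food share declines with income.
- **Household size**: categorical on 1–10, mode 4.
- **Patients**: 74% male; diagnosis mix schizophrenia 0.35 / hyperactive
  0.30 / anxiety 0.12 / other 0.23; 25% employed.  Caregivers: 86% female,
  71% mothers, 93% single.
- **OOP components**: each of the five components follows a two-part
  (hurdle) model — logistic participation, lognormal positive amount — so
  spending has realistic mass at zero and right skew.  Schizophrenia raises
  hospitalization and medicine spending; anxiety suppresses both (so that
  anxiety households rarely incur CHE); male patients and caregiver missed
  work days raise consultation/transport costs; employment lowers them.
- **`oop_scale`** multiplies every amount median and is the single
  calibration knob.  The default 0.3672 was fixed once by bisection at
  n = 50 000 so the scenario's CHE incidence at the 30% threshold sits at
  the study-scale 35%.
- A single master seed expands into named substreams (one per component),
  so adding a component never perturbs earlier draws, and datasets are
  byte-reproducible given the seed.

**Causal channels and what the regression can estimate.** The structural
equations are arranged so each default design-matrix covariate affects CHE
only through channels not blocked by the other covariates: patient sex,
employment and missed work days act on components *outside* the design
matrix (consultation, diagnostics, transport); diagnosis acts only on
hospitalization and medicines, which are *inside* it; income and household
size act mechanically through capacity to pay.  Without this discipline the
regression estimand and the counterfactual ground truth would differ by
construction.

**Ground truth** is defined by Monte-Carlo counterfactual contrast with
common random numbers: flip or unit-shift one covariate, re-simulate
everything downstream, push both samples through the full pipeline, and
difference the CHE probabilities.  The poverty line is estimated once on the
as-drawn sample and held fixed in the counterfactual arms: this matches the
household-level estimand of the regressions, whereas re-estimating the
sample-dependent line would measure a population-shift effect (growing every
household lowers the per-equivalent-adult line and largely cancels the
subsistence increase).  A covariate with no structural role returns exactly
zero.

**A finding worth knowing about.** Even with the design above, the
regression estimand does not coincide exactly with the counterfactual truth
for the *mechanical* money covariates (income, hospitalization, medicines):
the CHE indicator is a deterministic, regime-switching functional of the
expenditure vector (the food-substitution rule re-routes ~10% of households
onto a different latent index; the consumption floor truncates noise for the
poorest), so the single-equation logit/LPM is misspecified and its AMEs sit
roughly 10–30% below the structural contrast for those covariates —
systematically, not as sampling error.  Behavioral covariates (sex,
employment, household size, missed days) are recovered within sampling
error.  This is a caveat that transfers directly to real capacity-to-pay
analyses.  Consequently the parameter-recovery validation uses the
**known-response scenario**: realistic covariates from the structural
generator, response assigned from a logistic law with chosen mild
coefficients (prevalence ≈ 0.44, mid-range), where both the logit AME and
the LPM slope are consistent for the same truth.  Coefficients were chosen
mild *before* freezing by requiring the large-n OLS estimand to agree with
the true AME well within one n = 5000 robust standard error.

**Calibration** (`calibrate_to_incidence`) bisects `oop_scale` against the
simulated incidence with common random numbers (monotone up to simulation
granularity), returning the adjusted scenario and the achieved incidence; an
unreachable target raises with diagnostics instead of returning the closest
miss.

**What the generator does not emulate:** survey design effects (clustering,
stratification, weights beyond an optional column), item nonresponse and
reporting error, intra-year spending seasonality (annualization is a flat
×12, as in the instrument it mirrors), price inflation, and any correlation
between caregiver characteristics and spending.  Passing tests on generated
data therefore validate the *statistic and its implementation*, not the
behaviour of any particular real survey.

## Numerical conventions and problem sizes

- Exchange rate default 20.48 MXN/USD (mid-2018), configurable; the CHE
  statistic itself is currency-scale-invariant.
- Incidence ratios in exact rational arithmetic; poverty-line and capacity
  arithmetic in float64 with the brute-force oracle agreement tested at
  1e-12 relative tolerance.
- Logit convergence: statsmodels IRLS/Newton with a post-fit gradient check;
  `converged` is false unless estimates are finite and the score is
  numerically zero.
- Test problem sizes were chosen to exercise the asymptotics the claims rely
  on while staying desk-scale: oracle equivalence at n ≤ 50 × 200 datasets,
  parameter recovery at n = 5000 × 50 replications, stepwise operating
  characteristics at n = 5000 × 200 replications, calibration at n = 20 000,
  ground truth at n = 1–2 × 10⁵ draws.

## Known limitations

- The poverty line uses the nearest-rank window on the *sample*; with very
  small samples (n < ~20) the reference group is only a handful of
  households and the line is noisy — mirrored faithfully from the
  methodology rather than smoothed.
- Stepwise selection inherits all classical criticisms of stepwise
  procedures; the audit log makes runs reproducible but not inferentially
  valid after selection.
- The LPM can emit predicted probabilities outside [0, 1]; it is kept for
  comparability, with robust errors, not as the preferred model.
- No survey-weighted estimation, multilevel structure, or causal-inference
  machinery (matching, instruments): out of scope for the analysis this
  package implements.
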