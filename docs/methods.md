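# Methods

This note documents the statistical model implemented by `longscore`, the
design choices that were genuinely open, the synthetic-data generator's
assumptions, and the numerical details a maintainer should know.

## Scoring model

### Normative parameter models

Each (task, parameter) gets an ordinary-least-squares regression of the raw
value on `[1, age−60, (age−60)², 1{male}, 1{left-handed}]` fitted on
healthy controls, with a homoscedastic residual SD. Z-scores are
`(value − ŷ)/σ̂`. Assumptions: linear-plus-quadratic age trends, additive
sex/handedness effects, Gaussian homoscedastic residuals. Heteroscedastic
(age-dependent) variance and per-parameter power pre-transforms are not
modelled; the downstream mathematics only needs z to be approximately
standard normal in controls, which the pipeline verifies empirically
(training and held-out controls reproduce mean 0 ± 0.05, SD within
[0.95, 1.05]). Ages outside the fitted support trigger a warning and
extrapolate. Fitting requires ≥ 50 controls per parameter; a zero residual
SD (constant parameter) is an error, not a silent degenerate model.

Folding conventions: `higher_worse` keeps z (it may stay negative),
`lower_worse` negates, `two_sided` takes `|z|` — the only rule consistent
with "0 = best, large positive = poor" when both extremes are abnormal.
Note that the RSS step squares the folded values, so the sign conventions
matter for interpretation of individual parameters, not for the aggregate.

### RSS renormalization

Per-task RSS values of controls form the empirical reference. Quantile ranks
use Hazen plotting positions `(i − ½)/n` with linear interpolation between
order statistics and clamping to `[½n⁻¹, 1 − ½n⁻¹]`; the probit of the rank
is the Z-Task Score. The empirical map was chosen over a parametric chi or
Box–Cox fit because it makes no distributional assumption (inter-parameter
correlation makes the RSS distinctly non-chi) and is exactly testable. Two
consequences to keep in mind:

* **Tail saturation.** With a reference of n controls, Z-Task Scores cannot
  exceed `Φ⁻¹(1 − ½n⁻¹)` (≈ 3.0 at n = 600). Extremely impaired
  participants therefore pile up at the clamp, and changes between two
  already-clamped assessments are invisible. A larger reference cohort (or a
  parametric tail) extends the range; commercial normative systems that
  report task scores up to 6 evidently extrapolate beyond their reference.
* **Two-sample noise.** Scoring a fresh cohort against an estimated
  reference adds the reference's own sampling error; distributional checks
  of the scores should use a reference several times larger than the scored
  sample.

### One-sided Task Score

`TS = F½⁻¹(Φ(z))` with `F½(t) = erf(t/√2)` is the unique rank-preserving
map from N(0,1) to the half-normal. It reproduces every stated calibration
property in closed form: P(TS ≤ 1) = 2Φ(1)−1 = 68.3%, P(TS ≤ 2) = 95.4%,
P(TS < 1.96) = 95%, negatives map close to zero but positive. Impairment is
`TS ≥ 1.96` (inclusive), i.e. outside the 95% control envelope, giving a
designed 5% false-positive rate in healthy data.

## Change detection

Repeat control assessments define per-task difference distributions of
Z-Task Scores (second minus first). `SC = 1.96 × SD(diff)` is the standard
reliable-change envelope; the learning effect LE is the mean difference,
kept only when a paired t-test is significant at α = 0.05. Fixed LE values
(RVGR-D −0.72, RVGR-ND −0.76, SPS −0.43, TM −0.50 Z-Task units) are the
default configuration table and override estimation; passing
`le_table=None` estimates everything. A change is `improved` when
`Δz − LE < −SC`, `deteriorated` when `> +SC`; boundary-exact values (within
1e−9) are `no_change`. The Task-Score-space boundary is
`[T(z₁ − SC + LE), T(z₁ + SC + LE)]`: symmetric in z, curved and widening
in TS (a score far from 0 must change more), asymmetric when LE ≠ 0.

Individual p-values are the folded normal tails of the control-difference
model: `p = sf(|Δz_adj − μ|/σ)`, identical to "CDF, report 1−CDF above 0.5"
but exactly symmetric in floating point.

**Learning beyond two exposures.** Practice gains are treated as a one-time
effect realized at the second exposure: in multi-visit (consecutive) mode LE
is subtracted only from transitions that start at the first attended visit.
Repeat-assessment data beyond two visits would be needed to do better.

**Multi-visit calibration.** For the many-transition analysis the observed
p-values are pooled with 1000 simulated null p-values per transition — drawn
uniform on (0, 0.5], the null distribution of the folded statistic — and
Benjamini–Hochberg at α = 0.05 over the pooled family returns the largest
rejected p as the significance threshold. The published analysis this
emulates reported a threshold near 1.3 × 10⁻⁵; the exact construction of
its simulated family is not stated, so the threshold is seed- and
data-dependent here and is logged in the run manifest rather than treated
as a constant.

## Group statistics

One-sample t-tests of Z-Task Scores against 0 (first visit, last visit,
paired difference), BH-FDR across the whole emitted family. The family size
is computed from the data (60 when 10 task scores × 3 contrasts × 2 groups
are present) and a warning is raised when it differs from the expected 60.
Because the source analysis quotes both a BH threshold (≈ 0.0077) and a
Bonferroni-style footnote (p < 0.05/60), both decisions are reported side by
side (`significant_fdr`, `significant_bonferroni`) rather than silently
picking one. Cells with n < 2 or zero SD are emitted with NaN statistics and
excluded from the family.

## Synthetic cohort generator

Per participant, task unit (task × arm) and visit, each of the task's
parameters is

    value = μ(covariates) + λ^{repeat} · (√tf·trait + √(1−tf)·ε) + severity·sign

with exchangeable correlation ρ between a task's parameters.

| parameter | default | meaning / why |
|---|---|---|
| `n_controls` / `n_tia` / `n_migraine` | 600 / 48 / 28 | reference and the two recruited cohort sizes |
| `n_parameters` | 12 | within the battery's 10–20 features per task |
| `rho` | 0.3 | inter-parameter correlation; makes the RSS non-trivially non-chi |
| `trait_fraction` (tf) | 0.8 | stable share of variance ⇒ test-retest ICC ≈ 0.8, giving Z-Task difference SDs ≈ 0.85 and SC ≈ 1.7, the scale of published reliable-change thresholds |
| `learning_retention` (λ) | RVGR 0.82, TM 0.87, SPS 0.89 | deviation shrinkage on repeat exposure, calibrated so the fitted Z-Task LEs land near the published −0.72/−0.76/−0.43/−0.50 |
| `impairment_prevalence` | tia 0.25, migraine 0.12 | scalar or per-task-label table |
| `impairment_effect_sd` | 2.5 | per-parameter shift of truly-impaired units; puts them far outside the envelope, as observed impaired scores are |
| `improve/deteriorate_fraction` | tia 0.05/0.03, migraine 0.04/0.03 | per-task true change; keeps the per-assessment change rate near the observed ~8%, which sits just above the 5% noise floor, and skews toward improvement |
| `change_magnitude_sd` | 2.5 | severity drift over the follow-up year |
| `retention` | tia (1, .92, .81, .58); migraine (1, .75) | MCAR per-visit attendance reproducing declining denominators (48→~44→~39→~28) |
| `task_missing_rate` | 0.03 | per participant×task×visit missingness (varying task denominators) |
| visit schedules | tia 2wk/6wk/3mo/1yr; others 2wk/1yr | study design |

Design notes:

* **Learning is multiplicative.** Because the aggregate is a root sum of
  squares, an additive practice shift in any fixed direction *increases* the
  expected score; genuine practice gains can only appear as deviations
  shrinking toward the ideal. λ multiplies the trait+noise deviation (not
  the pathological severity) from the second attended exposure on.
* **Improvers are drawn from the impaired units.** Under folding,
  "better than normal" is not representable — a supernormal deviation on a
  two-sided parameter *raises* the RSS — so recovery means severity moving
  toward 0, not through it. Improvement labels are therefore assigned among
  truly-impaired units (marginal rate = configured fraction, requiring
  prevalence ≥ improve fraction); deterioration is assigned among the rest.
* **True-change drift advances with scheduled time** (a participant who
  skips the 6-week visit still deteriorates on schedule), while practice
  applies from the second visit actually performed.
* Impairment shifts respect each parameter's "worse" direction; for
  two-sided parameters the worse side is drawn per participant.
* Covariate effect sizes are drawn once from `structure_seed` (default 777)
  — the "world" is fixed by the config, not by the cohort seed — and all
  cohort randomness flows through one integer-indexed substream per
  participant, so outputs are byte-identical across platforms and cohort
  sizes don't perturb each other.
* Patient arm roles map onto control arms the way the cohort tables pair
  them: unaffected ↔ dominant, affected ↔ non-dominant.

What the generator does **not** emulate: skewed/heavy-tailed raw parameter
distributions, heteroscedastic aging, correlated impairment across tasks
(independent by default), outcome-dependent dropout (attrition is MCAR, as
the emulated study attributes dropout to loss of interest or moving), or
gradual multi-visit learning. Passing recovery tests therefore show the
pipeline is calibrated and consistent under its own assumptions — not that
real robotic-assessment data satisfy them.

## Numerical choices

* Task Score and its inverse are evaluated branch-wise through
  `erfinv`/`erfcinv` on the survival or CDF tail that is small, preserving
  full relative precision at both extremes; round-trips are exact to
  < 1e−12 across z ∈ [−6, 6] (tested at 1e−9).
* The folded p-value uses `sf(|·|)` rather than `min(CDF, 1−CDF)` for exact
  tail symmetry.
* BH step-up is implemented directly (stable sort; ties rejected together;
  threshold 0 when nothing is rejected) and cross-checked in tests against
  brute-force enumeration and statsmodels.
* Quantile interpolation uses `np.interp` on sorted reference values; exact
  ties in the reference are tolerated, an all-constant reference is an
  error.
* Envelope classification uses a 1e−9 tolerance so boundary-exact points are
  `no_change`.
* Degenerate inputs raise `NormativeError` with the offending parameter,
  task or participant named: missing covariates, < 50 controls per
  parameter, zero residual or difference SD, < 100 reference RSS values,
  < 30 paired controls, unpaired repeat records (an explicit `'drop'` mode
  exists for pipeline use where per-task missingness legitimately breaks
  pairs), non-positive Task Scores, p-values outside (0, 1].

## Problem sizes in the test suite

Statistical tests use sizes chosen to make their Monte-Carlo error small
relative to the asserted tolerances: 10⁶ draws for closed-form moment
checks; 10⁴ fresh controls for the null impairment rate (band 3.8–6.2%);
3 × 10³ paired controls for the null change rate; 100 seeded cohorts of the
study's size (48) for truth recovery, asserting that configured fractions
lie inside the 2.5–97.5 percentile band of detection-corrected per-seed
estimates (impairment corrected for the designed 5% false-positive rate,
change for the 2.5% per-tail rate). The change-recovery experiment disables
attrition so that every participant's final assessment reflects the full
configured drift; with attrition enabled, participants whose last visit is
at 3 months have only two-thirds of the drift and detection is
correspondingly lower — an attrition effect, not a miscalibration.

## Known limitations

* The empirical quantile map saturates at the reference tails (see above);
  changes between two saturated assessments are undetectable by design.
* SC uses the symmetric 1.96 × SD construction; percentile-based
  (potentially asymmetric) thresholds are not implemented.
* LE handling beyond the second exposure is a modelling choice (one-time
  gain), not an estimate.
* Group t-tests assume approximate normality of Z-Task Scores within
  cohorts; with patient cohorts clamped at the reference tails this is an
  approximation, which is one reason individual-level analysis is the
  primary output.
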