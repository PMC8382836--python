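# longscore

Normative scoring, impairment classification and learning-adjusted
significant-change detection for longitudinal multi-parameter behavioural
assessments — the analysis pattern used with robotic assessment batteries
(e.g. Kinarm-style reaching, bimanual and cognitive-motor tasks) in clinical
cohorts such as TIA and migraine followed over a year.

It is written for biostatisticians and clinical researchers who have
long-format task-parameter data (10–20 kinematic/temporal features per task,
per participant, arm and visit) plus a healthy-control reference cohort, and
who want individual-level answers: *is this participant impaired on this
task, and did they truly change between visits once practice effects are
accounted for?*

## The model

**Parameter z-scores.** Each raw parameter is regressed on age, age², sex
and handedness in healthy controls; `z = (value − ŷ(covariates)) / σ̂`
is mean-0/SD-1 in the reference population. Each z is folded so 0 is best
performance: unchanged, negated, or `|z|` depending on whether high, low, or
both extremes are abnormal.

**Z-Task Score.** The folded z's of one task are aggregated by their root
sum of squares, `RSS = √Σ zᵢ²`, and renormalized against the empirical
control RSS distribution (Hazen plotting positions `(i−½)/n`, probit
transform, clamped tails), giving a standard-normal per-task score.

**Task Score.** The one-sided score is the rank-preserving map from the
standard normal to the half-normal,

    TS = F½⁻¹(Φ(z)),     F½(t) = erf(t/√2),

so TS > 0 always, excellent performance ≈ 0, and for reference participants
68.3% of Task Scores fall below 1, 95.4% below 2.0, and 95% below the
impairment cut-off **TS ≥ 1.96** (outside the 95% control envelope).

**Significant change (SC) and learning effects (LE).** Repeat control
assessments give the per-task difference distribution of Z-Task Scores;
`SC = 1.96 × SD(diff)` is the 95% reliable-change envelope, and LE is the
mean practice gain for tasks where a paired t-test finds one (published
values for RVGR-D −0.72, RVGR-ND −0.76, SPS −0.43, TM −0.50 ship as the
default table). A change is significant when `|Δz − LE| > SC`; in Task-Score
space the envelope becomes the curved boundary pair
`T(z₁ − SC + LE), T(z₁ + SC + LE)`. Individual p-values are folded normal
tail probabilities of Δz; multi-visit designs calibrate a p threshold by
pooling observed p-values with simulated nulls under Benjamini–Hochberg FDR.

**Group statistics.** One-sample t-tests of Z-Task Scores against 0 at first
and last visits and on paired differences, with BH-FDR (and the Bonferroni
cut-off, side by side) over the full comparison family (60 tests for 10 task
scores × 3 contrasts × 2 groups).

A seeded synthetic-cohort generator (`longscore.synthetic`) emulates the
study structure — covariate-dependent parameters, test-retest reliability,
practice effects, per-task impairment prevalence, true longitudinal change,
visit schedules and attrition — with ground-truth labels for recovery
testing. See `docs/methods.md` for its assumptions and limits.

## Worked example

```python
from longscore import (CohortConfig, generate_controls, generate_cohort,
                       fit_scoring_model, score_tasks, fit_change_model,
                       evaluate_changes, change_matrix, impairment_table,
                       persistence_counts)
from longscore.synthetic import default_parameter_specs

cfg = CohortConfig()                                   # study-structure defaults
ctrl_obs, ctrl_cov = generate_controls(cfg, seed=7)
model = fit_scoring_model(ctrl_obs, ctrl_cov, default_parameter_specs(cfg))

scored_ctrl = score_tasks(ctrl_obs, ctrl_cov, model)
twice = scored_ctrl.groupby("participant_id")["visit"].nunique()
pairs = scored_ctrl[scored_ctrl["participant_id"].isin(twice[twice == 2].index)]
change_model = fit_change_model(pairs, unpaired="drop")
e = change_model["RVGR-D"]
print(f"RVGR-D: SC={e.sc:.2f}, LE={e.le:+.2f} (n={e.n} paired controls)")

tia_obs, tia_cov, truth = generate_cohort(cfg, "tia", seed=7)
scored = score_tasks(tia_obs, tia_cov, model)
print(impairment_table(scored).query("visit == '2wk'").head(4).to_string(index=False))
s = change_matrix(evaluate_changes(scored, change_model)).summary
print(f"changed >=1 task: {s['changed_ge1']}/{s['n_participants']} ({s['pct_changed_ge1']}%)")
print(f"changed >=2 tasks: {s['changed_ge2']}/{s['n_participants']} ({s['pct_changed_ge2']}%)")
```

prints

```
RVGR-D: SC=1.70, LE=-0.72 (n=282 paired controls)
group label visit  n_impaired  n_assessed  percent
  tia APM-A   2wk          15          46     32.6
  tia   BOB   2wk          15          47     31.9
  tia    OH   2wk           7          47     14.9
  tia   OHA   2wk          10          47     21.3
changed >=1 task: 27/48 (56%)
changed >=2 tasks: 9/48 (19%)
```

The fitted significant-change threshold for RVGR-D is 1.70 Z-Task-Score
units and the learning effect −0.72 (controls improve on re-test of this
cognitive-motor task). In the simulated TIA-like cohort roughly a third are
impaired on reaching/bimanual tasks at two weeks (configured 25% true
prevalence plus the designed 5% false-positive rate), and 56% of
participants change significantly on at least one of the ten task scores
between two weeks and one year — individual change that group-level t-tests
largely miss because improvements and deteriorations cancel.

The same pipeline is scriptable from the shell:

```bash
longscore simulate --seed 7 --out-dir runs/demo
longscore fit-normative --observations runs/demo/control_observations.csv \
    --covariates runs/demo/control_covariates.csv \
    --specs runs/demo/parameter_specs.csv --out-dir runs/demo
longscore score --observations runs/demo/patient_observations.csv \
    --covariates runs/demo/patient_covariates.csv \
    --model runs/demo/scoring_model.json --out-dir runs/demo
# ... change / group-stats / report, see `longscore --help`
```

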