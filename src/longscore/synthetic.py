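"""Seeded synthetic cohorts with the longitudinal study structure.

The generator emulates the data layout the scoring pipeline assumes: a large
healthy-control reference cohort with covariate-dependent task parameters
(a configurable fraction re-assessed once, providing the difference
distributions and practice effects for the change model), plus TIA-like and
migraine-like patient cohorts with per-task impairment prevalence, true
longitudinal improvement/deterioration, group-specific visit schedules
(2wk/6wk/3mo/1yr vs 2wk/1yr) and missing-completely-at-random per-visit
attrition that reproduces declining assessment denominators.

Generative model per participant, task unit (task x arm) and visit, for each
of the task's 10-20 parameters:

    value = mu(covariates) + lam^{repeat} * (sqrt(tf) * trait + sqrt(1-tf) * eps)
            + severity(visit) * worse_sign

* ``mu`` is linear in age (plus a small quadratic), sex and handedness, with
  coefficients fixed by ``structure_seed`` (the same "world" for every
  cohort drawn from one config).
* ``trait`` is a stable participant aptitude and ``eps`` fresh per-visit
  noise, both unit-variance with exchangeable correlation ``rho`` across the
  task's parameters; ``tf`` is the stable share of variance, which sets the
  test-retest reliability and hence the width of control difference scores.
* ``lam`` (<= 1, per task) shrinks deviations from the second exposure on:
  practice moves performance toward the ideal.  Learning is modelled
  multiplicatively because the aggregate score is a root-sum-square — an
  additive shift in any fixed direction can only inflate it.
* ``severity`` is the impairment mean shift in the parameter's "worse"
  direction: truly-impaired participant x task units start at
  ``impairment_effect_sd`` and true changers drift linearly across the
  schedule by ``change_magnitude_sd`` (improvers are drawn from the impaired
  units, so recovery moves scores toward — not through — the healthy range).

Ground-truth labels (impairment, change direction, retention) are returned
for recovery testing.  All randomness flows through integer-indexed
substreams (one per participant), so outputs are byte-identical for a given
seed regardless of platform or cohort slicing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .normative import DIRECTIONS, NormativeError
from .change import model_label

__all__ = [
    "DEFAULT_TASKS",
    "CohortConfig",
    "parameter_truth",
    "default_parameter_specs",
    "generate_controls",
    "generate_cohort",
    "TRUTH_COLUMNS",
]

#: Task battery: canonical control arm roles per task.  Reaching tasks are
#: scored per arm; position matching uses the non-dominant arm; the rest are
#: bimanual/whole-task scores.  Ten score units in total.
DEFAULT_TASKS: dict[str, tuple[str, ...]] = {
    "VGR": ("dominant", "nondominant"),
    "RVGR": ("dominant", "nondominant"),
    "APM": ("nondominant",),
    "BOB": ("bimanual",),
    "OH": ("bimanual",),
    "OHA": ("bimanual",),
    "TM": ("bimanual",),
    "SPS": ("bimanual",),
}

#: Patient arm roles replacing the canonical control roles.
_PATIENT_ARM = {"dominant": "unaffected", "nondominant": "affected", "bimanual": "bimanual"}

VISIT_SCHEDULES = {
    "control": ("2wk", "1yr"),
    "tia": ("2wk", "6wk", "3mo", "1yr"),
    "migraine": ("2wk", "1yr"),
}

_GROUP_CODE = {"control": 0, "tia": 1, "migraine": 2}

TRUTH_COLUMNS = ["participant_id", "task", "arm", "truly_impaired", "true_change"]


def _as_tuple(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


@dataclass
class CohortConfig:
    """Study-structure configuration; defaults mirror the emulated study."""

    # cohort sizes
    n_controls: int = 600
    n_tia: int = 48
    n_migraine: int = 28
    #: fraction of controls re-assessed at 1 year (difference-score sample)
    control_repeat_fraction: float = 0.5

    # task battery and noise structure
    tasks: dict = field(default_factory=lambda: dict(DEFAULT_TASKS))
    n_parameters: int = 12          # per task, within the 10-20 feature range
    rho: float = 0.3                # exchangeable inter-parameter correlation
    trait_fraction: float = 0.8     # stable share of deviation variance (test-retest)

    # covariates
    age_range: tuple = (40.0, 85.0)
    age_range_tia: tuple = (55.0, 85.0)
    age_range_migraine: tuple = (45.0, 80.0)
    prop_female: float = 0.5
    prop_right_handed: float = 0.93
    #: force one common age slope (units/yr) on every parameter; None draws
    #: heterogeneous per-parameter covariate effects from structure_seed
    age_slope: float | None = None
    structure_seed: int = 777

    # pathology and longitudinal truth
    impairment_prevalence: dict = field(
        default_factory=lambda: {"tia": 0.25, "migraine": 0.12}
    )
    impairment_effect_sd: float = 2.5
    improve_fraction: dict = field(
        default_factory=lambda: {"tia": 0.05, "migraine": 0.04}
    )
    deteriorate_fraction: dict = field(
        default_factory=lambda: {"tia": 0.03, "migraine": 0.03}
    )
    change_magnitude_sd: float = 2.5

    #: per-task multiplicative retention of deviations on repeat exposure
    #: (< 1 = practice effect); tasks absent here have none
    learning_retention: dict = field(
        default_factory=lambda: {"RVGR": 0.82, "TM": 0.87, "SPS": 0.89}
    )

    # attrition and missingness
    retention: dict = field(
        default_factory=lambda: {
            "control": (1.0, 1.0),
            "tia": (1.0, 0.92, 0.81, 0.58),
            "migraine": (1.0, 0.75),
        }
    )
    visit_schedules: dict = field(default_factory=lambda: dict(VISIT_SCHEDULES))
    task_missing_rate: float = 0.03

    def __post_init__(self) -> None:
        self.age_range = _as_tuple(self.age_range)
        self.age_range_tia = _as_tuple(self.age_range_tia)
        self.age_range_migraine = _as_tuple(self.age_range_migraine)
        self.tasks = {t: tuple(a) for t, a in self.tasks.items()}
        self.retention = {g: tuple(r) for g, r in self.retention.items()}
        self.visit_schedules = {g: tuple(v) for g, v in self.visit_schedules.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_controls < 100:
            raise NormativeError("n_controls: need at least 100 reference controls")
        if not 10 <= self.n_parameters <= 20:
            raise NormativeError("n_parameters: must lie in [10, 20]")
        if not 0 <= self.rho < 1:
            raise NormativeError("rho: must lie in [0, 1)")
        if not 0 <= self.trait_fraction < 1:
            raise NormativeError("trait_fraction: must lie in [0, 1)")
        for name in ("control_repeat_fraction", "task_missing_rate",
                     "prop_female", "prop_right_handed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise NormativeError(f"{name}: must lie in [0, 1]")
        for name in ("impairment_prevalence", "improve_fraction", "deteriorate_fraction"):
            table = getattr(self, name)
            for g, v in table.items():
                vals = v.values() if isinstance(v, Mapping) else [v]
                if not all(0 <= x <= 1 for x in vals):
                    raise NormativeError(f"{name}[{g!r}]: fractions must lie in [0, 1]")
        for g, probs in self.retention.items():
            if not all(0 < r <= 1 for r in probs):
                raise NormativeError(f"retention[{g!r}]: probabilities must lie in (0, 1]")
            if g in self.visit_schedules and len(probs) != len(self.visit_schedules[g]):
                raise NormativeError(
                    f"retention[{g!r}]: needs one probability per scheduled visit"
                )
        for t, lam in self.learning_retention.items():
            if not 0 < lam <= 1:
                raise NormativeError(f"learning_retention[{t!r}]: must lie in (0, 1]")
        if self.impairment_effect_sd < 0 or self.change_magnitude_sd < 0:
            raise NormativeError("impairment_effect_sd / change_magnitude_sd: must be >= 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        return cls.from_dict(data or {})

    # -- derived structure -------------------------------------------------
    def units(self, group: str) -> list[tuple[str, str]]:
        """(task, arm) score units for a group, in deterministic order."""
        out = []
        for task in sorted(self.tasks):
            for arm in self.tasks[task]:
                out.append((task, arm if group == "control" else _PATIENT_ARM[arm]))
        return out

    def prevalence(self, group: str, task: str, arm: str) -> float:
        return _lookup(self.impairment_prevalence.get(group, 0.0), task, arm)

    def fraction(self, table: Mapping, group: str, task: str, arm: str) -> float:
        return _lookup(table.get(group, 0.0), task, arm)


def _lookup(value, task: str, arm: str) -> float:
    if isinstance(value, Mapping):
        return float(value.get(model_label(task, arm), value.get(task, 0.0)))
    return float(value)


# ---------------------------------------------------------------------------
# fixed "world" structure


def parameter_truth(config: CohortConfig) -> pd.DataFrame:
    """True per-parameter covariate coefficients and directions.

    Fixed by ``structure_seed`` only, so every cohort generated from the same
    config shares one world; the master seed never changes the coefficients.
    """
    rows = []
    for ti, task in enumerate(sorted(config.tasks)):
        rng = np.random.default_rng(np.random.SeedSequence((config.structure_seed, ti)))
        for pi in range(config.n_parameters):
            direction = DIRECTIONS[pi % len(DIRECTIONS)]
            age = rng.normal(0.02, 0.01) if config.age_slope is None else config.age_slope
            rows.append(
                dict(
                    task=task,
                    parameter=f"p{pi:02d}",
                    direction=direction,
                    intercept=float(rng.normal(0.0, 1.0)),
                    age=float(age),
                    age2=float(rng.normal(0.0, 2e-4)),
                    sex_male=float(rng.normal(0.0, 0.3)),
                    hand_left=float(rng.normal(0.0, 0.2)),
                )
            )
    return pd.DataFrame(rows)


def default_parameter_specs(config: CohortConfig) -> pd.DataFrame:
    """Parameter spec table (task, parameter, direction, units) for the world."""
    truth = parameter_truth(config)
    specs = truth[["task", "parameter", "direction"]].copy()
    specs["units"] = "a.u."
    return specs


# ---------------------------------------------------------------------------
# generation


def _draw_covariates(rng, config: CohortConfig, group: str) -> dict:
    lo, hi = {
        "control": config.age_range,
        "tia": config.age_range_tia,
        "migraine": config.age_range_migraine,
    }[group]
    return dict(
        age=float(rng.uniform(lo, hi)),
        sex="female" if rng.uniform() < config.prop_female else "male",
        handedness="right" if rng.uniform() < config.prop_right_handed else "left",
    )


def _correlated(rng, n_params: int, rho: float) -> np.ndarray:
    """Unit-variance vector with exchangeable correlation rho."""
    shared = rng.normal()
    indep = rng.normal(size=n_params)
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep


def _participant_rows(
    rng,
    config: CohortConfig,
    group: str,
    pid: str,
    cov: dict,
    truth_by_task: Mapping,
    schedule: list[str],
    attended: list[int],
    coef: Mapping,
):
    """Observation rows for one participant; consumes rng in a fixed order.

    ``attended`` holds schedule indices: true-change drift advances with
    scheduled time, while practice effects kick in from the second visit the
    participant actually performed.
    """
    n = config.n_parameters
    tf = config.trait_fraction
    rows = []
    for task, arm in config.units(group):
        c = coef[task]
        mu = (
            c["intercept"]
            + c["age"] * (cov["age"] - 60.0)
            + c["age2"] * (cov["age"] - 60.0) ** 2
            + c["sex_male"] * (cov["sex"] == "male")
            + c["hand_left"] * (cov["handedness"] == "left")
        )
        worse = c["worse_base"].copy()
        two_sided = c["two_sided_mask"]
        if two_sided.any():
            worse[two_sided] = np.where(rng.uniform(size=int(two_sided.sum())) < 0.5, 1.0, -1.0)
        trait = _correlated(rng, n, config.rho)
        lam = config.learning_retention.get(task, 1.0)
        impaired, change = truth_by_task[(task, arm)]
        s0 = config.impairment_effect_sd if impaired else 0.0
        drift = {"improve": -1.0, "deteriorate": 1.0, "none": 0.0}[change] * config.change_magnitude_sd
        n_sched = len(schedule)
        for ai, si in enumerate(attended):
            visit = schedule[si]
            eps = _correlated(rng, n, config.rho)
            retain = lam if ai > 0 else 1.0
            frac = si / (n_sched - 1) if n_sched > 1 else 0.0
            severity = max(s0 + frac * drift, 0.0)
            dev = retain * (np.sqrt(tf) * trait + np.sqrt(1.0 - tf) * eps)
            values = mu + dev + severity * worse
            # per-visit dropout and per-task missingness (MCAR)
            if rng.uniform() < config.task_missing_rate:
                continue
            rows.append((pid, group, visit, task, arm, values))
    return rows


def _precompute_coef(config: CohortConfig) -> dict:
    truth = parameter_truth(config)
    coef = {}
    for task, grp in truth.groupby("task", sort=True):
        base = np.where(grp["direction"] == "lower_worse", -1.0, 1.0)
        coef[task] = {
            "intercept": grp["intercept"].to_numpy(),
            "age": grp["age"].to_numpy(),
            "age2": grp["age2"].to_numpy(),
            "sex_male": grp["sex_male"].to_numpy(),
            "hand_left": grp["hand_left"].to_numpy(),
            "parameters": grp["parameter"].to_numpy(),
            "worse_base": base.astype(float),
            "two_sided_mask": (grp["direction"] == "two_sided").to_numpy(),
        }
    return coef


def _assemble(config: CohortConfig, all_rows, coef) -> pd.DataFrame:
    pid_l, grp_l, vis_l, task_l, arm_l, par_l, val_l = [], [], [], [], [], [], []
    n = config.n_parameters
    for pid, group, visit, task, arm, values in all_rows:
        pid_l.append(np.repeat(pid, n))
        grp_l.append(np.repeat(group, n))
        vis_l.append(np.repeat(visit, n))
        task_l.append(np.repeat(task, n))
        arm_l.append(np.repeat(arm, n))
        par_l.append(coef[task]["parameters"])
        val_l.append(values)
    if not all_rows:
        return pd.DataFrame(
            columns=["participant_id", "group", "visit", "task", "arm", "parameter", "value"]
        )
    return pd.DataFrame(
        {
            "participant_id": np.concatenate(pid_l),
            "group": np.concatenate(grp_l),
            "visit": np.concatenate(vis_l),
            "task": np.concatenate(task_l),
            "arm": np.concatenate(arm_l),
            "parameter": np.concatenate(par_l),
            "value": np.round(np.concatenate(val_l), 9),
        }
    )


def _rng_for(seed: int, group: str, index: int):
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _GROUP_CODE[group], int(index)))
    )


def generate_controls(config: CohortConfig, seed: int):
    """Healthy-control reference cohort.

    Returns ``(observations, covariates)``.  Every control is assessed at the
    first scheduled visit; a ``control_repeat_fraction`` subset returns for
    the second visit (with practice effects applied), providing the paired
    sample for the change model.
    """
    coef = _precompute_coef(config)
    schedule = list(config.visit_schedules["control"])
    rows, covs = [], []
    for i in range(config.n_controls):
        rng = _rng_for(seed, "control", i)
        pid = f"C{i:04d}"
        cov = _draw_covariates(rng, config, "control")
        covs.append(dict(participant_id=pid, **cov))
        repeat = rng.uniform() < config.control_repeat_fraction
        attended = list(range(len(schedule))) if repeat else [0]
        truth_by_task = {unit: (False, "none") for unit in config.units("control")}
        rows.extend(
            _participant_rows(rng, config, "control", pid, cov, truth_by_task,
                              schedule, attended, coef)
        )
    obs = _assemble(config, rows, coef)
    return obs, pd.DataFrame(covs)


def generate_cohort(config: CohortConfig, group: str, seed: int):
    """Patient cohort with ground truth.

    Returns ``(observations, covariates, truth)``.  Truth has one row per
    participant x task unit (``TRUTH_COLUMNS``); retention thinning removes
    whole visits at the configured per-visit probabilities.
    """
    if group not in ("tia", "migraine"):
        raise NormativeError(f"group must be 'tia' or 'migraine', got {group!r}")
    coef = _precompute_coef(config)
    schedule = list(config.visit_schedules[group])
    retention = config.retention[group]
    n = {"tia": config.n_tia, "migraine": config.n_migraine}[group]
    prefix = {"tia": "T", "migraine": "M"}[group]
    rows, covs, truth_rows = [], [], []
    for i in range(n):
        rng = _rng_for(seed, group, i)
        pid = f"{prefix}{i:04d}"
        cov = _draw_covariates(rng, config, group)
        covs.append(dict(participant_id=pid, **cov))
        truth_by_task = {}
        for task, arm in config.units(group):
            prev = config.prevalence(group, task, arm)
            f_imp = config.fraction(config.improve_fraction, group, task, arm)
            f_det = config.fraction(config.deteriorate_fraction, group, task, arm)
            impaired = rng.uniform() < prev
            # improvers come from the impaired units so that the marginal
            # improvement fraction is f_imp; deterioration fills the rest
            improve = impaired and prev > 0 and rng.uniform() < min(f_imp / prev, 1.0)
            deteriorate = (not improve) and f_imp < 1 and rng.uniform() < f_det / (1.0 - f_imp)
            change = "improve" if improve else ("deteriorate" if deteriorate else "none")
            truth_by_task[(task, arm)] = (impaired, change)
            truth_rows.append(
                dict(participant_id=pid, task=task, arm=arm,
                     truly_impaired=impaired, true_change=change)
            )
        attended = [si for si, r in enumerate(retention) if rng.uniform() < r]
        rows.extend(
            _participant_rows(rng, config, group, pid, cov, truth_by_task,
                              schedule, attended, coef)
        )
    obs = _assemble(config, rows, coef)
    return obs, pd.DataFrame(covs), pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
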