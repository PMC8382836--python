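"""Normative reference models for task parameters.

Raw task-parameter values (reaction times, path lengths, ...) are measured in
disparate units and depend strongly on age, sex and handedness.  This module
fits, per (task, parameter), an ordinary-least-squares regression of the raw
value on age, age squared, sex and handedness in a healthy-control reference
cohort, and converts any observation into a covariate-adjusted z-score

    z = (value - predicted(covariates)) / residual_sd

with mean 0 and SD 1 in the reference population.  Each z is then *folded*
according to the parameter's direction convention so that 0 is best
performance and large positive values are poor performance:

    higher_worse -> z          lower_worse -> -z          two_sided -> |z|

Folded parameter z-scores are the inputs to the per-task aggregate scores in
:mod:`longscore.task_score`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DIRECTIONS",
    "OBSERVATION_COLUMNS",
    "COVARIATE_COLUMNS",
    "SPEC_COLUMNS",
    "ParameterModel",
    "NormativeModel",
    "fit_normative_model",
    "parameter_zscore",
    "fold_parameter",
    "zscore_observations",
    "read_observations",
    "read_covariates",
    "read_parameter_specs",
]

DIRECTIONS = ("higher_worse", "lower_worse", "two_sided")

GROUPS = ("control", "tia", "migraine")
VISITS = ("2wk", "6wk", "3mo", "1yr")
ARMS = ("dominant", "nondominant", "affected", "unaffected", "bimanual")

OBSERVATION_COLUMNS = [
    "participant_id", "group", "visit", "task", "arm", "parameter", "value",
]
COVARIATE_COLUMNS = ["participant_id", "age", "sex", "handedness"]
SPEC_COLUMNS = ["task", "parameter", "direction", "units"]

# Age is centred before squaring to keep the design matrix well conditioned.
AGE_CENTER = 60.0

MIN_CONTROLS_PER_PARAMETER = 50


class NormativeError(ValueError):
    """Raised for invalid inputs to normative fitting or scoring."""


@dataclass
class ParameterModel:
    """Fitted reference model for one (task, parameter).

    Coefficients are for the design
    ``[1, age - 60, (age - 60)^2, sex == male, handedness == left]``.
    """

    task: str
    parameter: str
    direction: str
    coef: dict[str, float]
    stderr: dict[str, float]
    residual_sd: float
    n: int
    age_min: float
    age_max: float
    units: str = ""

    def predict(self, cov: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(cov)
        beta = np.array([self.coef[c] for c in _DESIGN_COLS])
        return X @ beta


_DESIGN_COLS = ["intercept", "age", "age2", "sex_male", "hand_left"]


def _design_matrix(cov: pd.DataFrame) -> np.ndarray:
    age = np.asarray(cov["age"], dtype=float) - AGE_CENTER
    sex_male = (np.asarray(cov["sex"]) == "male").astype(float)
    hand_left = (np.asarray(cov["handedness"]) == "left").astype(float)
    return np.column_stack([np.ones_like(age), age, age ** 2, sex_male, hand_left])


@dataclass
class NormativeModel:
    """Collection of per-parameter reference models, keyed by (task, parameter)."""

    parameters: dict[tuple[str, str], ParameterModel] = field(default_factory=dict)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self.parameters

    def __getitem__(self, key: tuple[str, str]) -> ParameterModel:
        key = tuple(key)
        if key not in self.parameters:
            raise NormativeError(f"no normative model for task/parameter {key!r}")
        return self.parameters[key]

    @property
    def tasks(self) -> list[str]:
        return sorted({t for t, _ in self.parameters})

    def parameters_for(self, task: str) -> list[str]:
        return sorted(p for t, p in self.parameters if t == task)

    def to_dict(self) -> dict:
        out: dict[str, dict[str, dict]] = {}
        for (task, parameter), pm in sorted(self.parameters.items()):
            out.setdefault(task, {})[parameter] = asdict(pm)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormativeModel":
        params = {}
        for task, by_param in d.items():
            for parameter, pd_ in by_param.items():
                params[(task, parameter)] = ParameterModel(**pd_)
        return cls(params)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormativeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting


def fit_normative_model(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    specs: pd.DataFrame,
    min_controls: int = MIN_CONTROLS_PER_PARAMETER,
) -> NormativeModel:
    """Fit per-parameter covariate regressions on healthy-control observations.

    Parameters
    ----------
    observations
        Long-format control observations with columns ``OBSERVATION_COLUMNS``.
        Only the first visit of each participant should be supplied (repeat
        visits carry practice effects and would bias the reference).
    covariates
        One row per participant: ``participant_id, age, sex, handedness``.
    specs
        One row per (task, parameter): ``task, parameter, direction, units``.
    min_controls
        Minimum number of distinct control participants per parameter.
    """
    obs = observations
    _check_columns(obs, OBSERVATION_COLUMNS, "observations")
    _check_columns(covariates, COVARIATE_COLUMNS, "covariates")
    _check_columns(specs, SPEC_COLUMNS, "parameter specs")

    bad_dir = set(specs["direction"]) - set(DIRECTIONS)
    if bad_dir:
        raise NormativeError(f"unknown parameter directions: {sorted(bad_dir)}")
    spec_map = {
        (r.task, r.parameter): (r.direction, r.units)
        for r in specs.itertuples(index=False)
    }

    missing_cov = sorted(set(obs["participant_id"]) - set(covariates["participant_id"]))
    if missing_cov:
        raise NormativeError(
            f"covariates missing for participants: {missing_cov}"
        )
    cov_ix = covariates.drop_duplicates("participant_id").set_index("participant_id")

    model = NormativeModel()
    for (task, parameter), grp in obs.groupby(["task", "parameter"], sort=True):
        if (task, parameter) not in spec_map:
            raise NormativeError(
                f"observations contain task/parameter {(task, parameter)!r} "
                "with no entry in the parameter specs"
            )
        n_participants = grp["participant_id"].nunique()
        if n_participants < min_controls:
            raise NormativeError(
                f"parameter {task}/{parameter}: only {n_participants} control "
                f"participants (need >= {min_controls})"
            )
        cov = cov_ix.loc[grp["participant_id"]].reset_index()
        X = _design_matrix(cov)
        y = np.asarray(grp["value"], dtype=float)
        res = sm.OLS(y, X).fit()
        dof = len(y) - X.shape[1]
        resid_sd = float(np.sqrt(res.ssr / dof))
        if not np.isfinite(resid_sd) or resid_sd <= 1e-12 * max(1.0, np.abs(y).max()):
            raise NormativeError(
                f"parameter {task}/{parameter}: residual SD is zero or degenerate"
            )
        direction, units = spec_map[(task, parameter)]
        model.parameters[(task, parameter)] = ParameterModel(
            task=task,
            parameter=parameter,
            direction=direction,
            coef=dict(zip(_DESIGN_COLS, map(float, res.params))),
            stderr=dict(zip(_DESIGN_COLS, map(float, res.bse))),
            residual_sd=resid_sd,
            n=int(n_participants),
            age_min=float(cov["age"].min()),
            age_max=float(cov["age"].max()),
            units=str(units),
        )
    return model


# ---------------------------------------------------------------------------
# scoring


def parameter_zscore(
    value, cov: pd.DataFrame | Mapping, model: NormativeModel, task: str, parameter: str
):
    """Covariate-adjusted signed z-score(s) for raw value(s) of one parameter."""
    pm = model[(task, parameter)]
    if not isinstance(cov, pd.DataFrame):
        cov = pd.DataFrame([dict(cov)])
    age = np.asarray(cov["age"], dtype=float)
    if (age < pm.age_min).any() or (age > pm.age_max).any():
        warnings.warn(
            f"age outside normative support [{pm.age_min:.0f}, {pm.age_max:.0f}] "
            f"for {task}/{parameter}; extrapolating",
            stacklevel=2,
        )
    z = (np.asarray(value, dtype=float) - pm.predict(cov)) / pm.residual_sd
    return z if np.ndim(value) else float(z[0] if np.ndim(z) else z)


def fold_parameter(z, direction: str):
    """Fold a signed z onto the one-sided scale (0 best, positive worse)."""
    if direction not in DIRECTIONS:
        raise NormativeError(f"unknown direction {direction!r}")
    z = np.asarray(z, dtype=float)
    if direction == "higher_worse":
        out = z
    elif direction == "lower_worse":
        out = -z
    else:
        out = np.abs(z)
    return float(out) if out.ndim == 0 else out


def zscore_observations(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    model: NormativeModel,
) -> pd.DataFrame:
    """Attach signed and folded z-scores to a long observation table.

    Returns a copy of ``observations`` with ``z`` and ``z_folded`` columns.
    Row order of the input is preserved; the result is independent of it.
    """
    obs = observations
    _check_columns(obs, OBSERVATION_COLUMNS, "observations")
    missing_cov = sorted(set(obs["participant_id"]) - set(covariates["participant_id"]))
    if missing_cov:
        raise NormativeError(f"covariates missing for participants: {missing_cov}")
    cov_ix = covariates.drop_duplicates("participant_id").set_index("participant_id")

    out = obs.copy()
    z = np.full(len(obs), np.nan)
    folded = np.full(len(obs), np.nan)
    grouped = obs.groupby(["task", "parameter"], sort=False)
    for (task, parameter), grp in grouped:
        pm = model[(task, parameter)]
        cov = cov_ix.loc[grp["participant_id"]].reset_index()
        zg = (np.asarray(grp["value"], dtype=float) - pm.predict(cov)) / pm.residual_sd
        idx = grp.index.to_numpy()
        pos = out.index.get_indexer(idx)
        z[pos] = zg
        folded[pos] = fold_parameter(zg, pm.direction)
    out["z"] = z
    out["z_folded"] = folded
    return out


# ---------------------------------------------------------------------------
# CSV interfaces


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NormativeError(f"{what} table is missing columns {missing}")


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, OBSERVATION_COLUMNS, "observations")
    dup = df.duplicated(["participant_id", "visit", "task", "arm", "parameter"])
    if dup.any():
        raise NormativeError(
            f"{int(dup.sum())} duplicate (participant, visit, task, arm, parameter) keys"
        )
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, COVARIATE_COLUMNS, "covariates")
    return df


def read_parameter_specs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SPEC_COLUMNS, "parameter specs")
    return df
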