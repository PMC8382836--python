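"""Per-task aggregate scores: RSS, Z-Task Score and one-sided Task Score.

The folded parameter z-scores of one task are combined by their root sum of
squares (RSS).  Because parameters are correlated and their number varies by
task, the raw RSS is not on any common scale; it is renormalized against the
empirical distribution of control RSS values for the same task (quantile map
with Hazen plotting positions, probit transform), giving the Z-Task Score —
standard normal in the reference population.

The Z-Task Score is finally compressed onto a strictly positive one-sided
scale.  The Task Score

    TS = F_half^{-1}( Phi(z) )        F_half(t) = erf(t / sqrt 2)

is the rank-preserving map from the standard normal to the half-normal
distribution: excellent performance maps close to 0, and for a reference
participant 68.3% of Task Scores fall below 1, 95.4% below 2.0 and 95%
below the impairment cut-off 1.96.  Scores at or above 1.96 (outside the 95%
control envelope) are classified impaired.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .normative import (
    NormativeError,
    NormativeModel,
    fit_normative_model,
    zscore_observations,
)

__all__ = [
    "IMPAIRMENT_THRESHOLD",
    "RSSReference",
    "ScoringModel",
    "compute_rss",
    "fit_rss_reference",
    "z_task_score",
    "task_score",
    "inverse_task_score",
    "is_impaired",
    "score_tasks",
    "fit_scoring_model",
]

IMPAIRMENT_THRESHOLD = 1.96

_SQRT2 = math.sqrt(2.0)

#: Task Score of a reference-median performance, T(0) = Phi^{-1}(0.75).
TS_MEDIAN = _SQRT2 * float(special.erfinv(0.5))

SCORED_COLUMNS = [
    "participant_id", "group", "visit", "task", "arm",
    "rss", "z_task_score", "task_score", "impaired",
]


def compute_rss(folded_z) -> float:
    """Root sum of squares of a task's folded parameter z-scores."""
    z = np.asarray(folded_z, dtype=float)
    if z.size == 0:
        raise NormativeError("cannot compute RSS of an empty parameter vector (task not assessed)")
    if not np.isfinite(z).all():
        raise NormativeError("non-finite folded z-scores in RSS input")
    return float(np.sqrt(np.sum(np.square(z))))


@dataclass
class RSSReference:
    """Empirical control RSS distribution for one task.

    Quantile ranks use Hazen plotting positions (i - 0.5)/n and are clamped
    to [0.5/n, 1 - 0.5/n], so out-of-range queries map to finite tails.
    """

    values: np.ndarray  # sorted, ascending
    task: str = ""

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def ranks(self) -> np.ndarray:
        n = self.n
        return (np.arange(1, n + 1) - 0.5) / n

    def rank(self, rss):
        """Interpolated, clamped quantile rank of rss within the reference."""
        r = np.interp(np.asarray(rss, dtype=float), self.values, self.ranks)
        return float(r) if np.ndim(rss) == 0 else r

    def to_dict(self) -> dict:
        return {"task": self.task, "values": [float(v) for v in self.values]}

    @classmethod
    def from_dict(cls, d) -> "RSSReference":
        return cls(values=np.asarray(d["values"], dtype=float), task=d.get("task", ""))


def fit_rss_reference(control_rss, task: str = "", min_n: int = 100) -> RSSReference:
    """Build the empirical reference from control RSS values (>= 100 required)."""
    vals = np.asarray(control_rss, dtype=float)
    if vals.size < min_n:
        raise NormativeError(
            f"RSS reference for task {task or '<unnamed>'}: {vals.size} control values "
            f"(need >= {min_n})"
        )
    if (vals < 0).any():
        raise NormativeError("RSS values must be non-negative")
    if np.ptp(vals) == 0:
        raise NormativeError(
            f"RSS reference for task {task or '<unnamed>'} is degenerate (all values identical)"
        )
    return RSSReference(values=vals, task=task)


def z_task_score(rss, ref: RSSReference):
    """Probit of the reference rank: standard normal over the reference cohort."""
    return special.ndtri(ref.rank(rss))


def task_score(z):
    """One-sided Task Score: rank-preserving normal -> half-normal map.

    Evaluated branch-wise through survival/CDF tails so that both extremes
    retain full relative precision (round-trips with
    :func:`inverse_task_score` to better than 1e-9 across z in [-6, 6]).
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    hi = z >= 0
    # upper branch: erfc(TS/sqrt2) = sf(z), sf small and relatively accurate
    out[hi] = _SQRT2 * special.erfcinv(special.ndtr(-z[hi]))
    # lower branch: erf(TS/sqrt2) = cdf(z), cdf small and relatively accurate
    out[~hi] = _SQRT2 * special.erfinv(special.ndtr(z[~hi]))
    return float(out) if out.ndim == 0 else out


def inverse_task_score(ts):
    """Z-Task Score whose one-sided Task Score equals ``ts`` (ts > 0)."""
    ts = np.asarray(ts, dtype=float)
    if (ts <= 0).any():
        raise NormativeError("Task Scores are strictly positive")
    out = np.empty_like(ts)
    hi = ts >= TS_MEDIAN
    out[hi] = -special.ndtri(special.erfc(ts[hi] / _SQRT2))
    out[~hi] = special.ndtri(special.erf(ts[~hi] / _SQRT2))
    return float(out) if out.ndim == 0 else out


def is_impaired(ts):
    """Impairment flag: Task Score at or beyond the 95% control envelope."""
    ts = np.asarray(ts, dtype=float)
    if (ts <= 0).any():
        raise NormativeError("Task Scores are strictly positive")
    out = ts >= IMPAIRMENT_THRESHOLD
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# end-to-end scoring


@dataclass
class ScoringModel:
    """Normative parameter models plus per-task RSS references; serializable."""

    normative: NormativeModel
    rss_references: dict[str, RSSReference] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "normative": self.normative.to_dict(),
            "rss_references": {t: r.to_dict() for t, r in sorted(self.rss_references.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScoringModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            normative=NormativeModel.from_dict(payload["normative"]),
            rss_references={
                t: RSSReference.from_dict(d) for t, d in payload["rss_references"].items()
            },
        )


def _task_rss_table(zscored: pd.DataFrame, model: NormativeModel) -> pd.DataFrame:
    """Collapse folded parameter z-scores to one RSS per participant/visit/task/arm.

    A task/visit with an incomplete parameter set (relative to the fitted
    model) is dropped and counted as not assessed.
    """
    expected = {t: len(model.parameters_for(t)) for t in model.tasks}
    keys = ["participant_id", "group", "visit", "task", "arm"]
    agg = (
        zscored.groupby(keys, sort=True)["z_folded"]
        .agg(rss=lambda v: float(np.sqrt(np.sum(np.square(v)))), n_params="size")
        .reset_index()
    )
    complete = agg["n_params"] == agg["task"].map(expected)
    return agg.loc[complete, keys + ["rss"]].reset_index(drop=True)


def score_tasks(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    model: ScoringModel,
) -> pd.DataFrame:
    """Full scoring pipeline: raw observations -> Task Scores and impairment flags.

    Returns one row per (participant, visit, task, arm) with columns
    ``SCORED_COLUMNS``.  Tasks with missing parameters are omitted (not
    assessed); the output is invariant to input row order.
    """
    zscored = zscore_observations(observations, covariates, model.normative)
    table = _task_rss_table(zscored, model.normative)
    missing_refs = sorted(set(table["task"]) - set(model.rss_references))
    if missing_refs:
        raise NormativeError(f"no RSS reference for tasks: {missing_refs}")
    z = np.empty(len(table))
    for task, grp in table.groupby("task", sort=False):
        ref = model.rss_references[task]
        z[table.index.get_indexer(grp.index)] = z_task_score(
            grp["rss"].to_numpy(), ref
        )
    table["z_task_score"] = z
    table["task_score"] = task_score(z)
    table["impaired"] = table["task_score"] >= IMPAIRMENT_THRESHOLD
    return table[SCORED_COLUMNS]


def fit_scoring_model(
    control_observations: pd.DataFrame,
    control_covariates: pd.DataFrame,
    specs: pd.DataFrame,
    reference_visit: str = "2wk",
) -> ScoringModel:
    """Fit the normative models and RSS references from a control cohort.

    Only the first (``reference_visit``) assessment of each control enters the
    reference; repeat visits carry practice effects and are reserved for the
    change model.
    """
    first = control_observations[control_observations["visit"] == reference_visit]
    normative = fit_normative_model(first, control_covariates, specs)
    zscored = zscore_observations(first, control_covariates, normative)
    table = _task_rss_table(zscored, normative)
    refs = {
        task: fit_rss_reference(grp["rss"].to_numpy(), task=task)
        for task, grp in table.groupby("task", sort=True)
    }
    return ScoringModel(normative=normative, rss_references=refs)
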