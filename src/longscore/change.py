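"""Significant-change detection between repeated assessments.

Repeat assessments of healthy controls define, per task score, the
distribution of Z-Task-Score differences (second minus first).  From it the
change model derives

* the significant-change threshold SC = 1.96 x SD of control differences
  (the 95% reliable-change envelope on the z-difference scale), and
* the expected learning effect LE: the mean control difference, retained only
  when a paired t-test finds it significant, otherwise 0.  Published LE
  values for tasks with strong practice effects (RVGR-D -0.72, RVGR-ND
  -0.76, SPS -0.43, TM -0.50 in Z-Task-Score units) ship as the default
  fixed table and override estimation.

A patient's change is evaluated in z-space: delta = z_last - z_first,
adjusted = delta - LE; |adjusted| > SC flags significant improvement
(negative) or deterioration (positive).  In Task-Score space the same
envelope becomes the curved boundary pair

    lower = T(z_first - SC + LE),   upper = T(z_first + SC + LE)

whose width grows with distance from 0 (scores far from the reference median
must change more to be significant), and which is asymmetric when LE != 0.

Individual p-values come from the Normal CDF of the control-difference
distribution, with the upper tail folded: values above 0.5 are reported as
1 - CDF, so p is always a small-is-extreme number in (0, 0.5].  For
multi-visit designs the per-transition p-values are pooled with simulated
null p-values and a Benjamini-Hochberg step-up yields the calibrated
significance threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .normative import NormativeError
from .task_score import inverse_task_score, task_score
from .group_stats import bh_adjust

__all__ = [
    "DEFAULT_LEARNING_EFFECTS",
    "arm_class",
    "score_label",
    "ChangeEntry",
    "ChangeModel",
    "fit_change_model",
    "individual_change_p",
    "sc_boundary",
    "classify_change",
    "evaluate_changes",
    "calibrate_multivisit_threshold",
]

#: Fixed learning effects (Z-Task-Score units, second minus first assessment)
#: for the tasks with established practice gains.
DEFAULT_LEARNING_EFFECTS = {
    "RVGR-D": -0.72,
    "RVGR-ND": -0.76,
    "SPS": -0.43,
    "TM": -0.50,
}

SC_MULTIPLIER = 1.96
MIN_PAIRED_CONTROLS = 30
_BOUNDARY_TOL = 1e-9

# Patient arm roles are paired with the control arm whose column they share in
# the cohort tables: unaffected with dominant, affected with non-dominant.
_ARM_CLASS = {
    "dominant": "dominant",
    "unaffected": "dominant",
    "nondominant": "nondominant",
    "affected": "nondominant",
    "bimanual": "bimanual",
}
_ARM_SUFFIX = {
    "dominant": "D",
    "nondominant": "ND",
    "affected": "A",
    "unaffected": "UA",
}


def arm_class(arm: str) -> str:
    """Collapse patient arm roles onto the control reference arm classes."""
    try:
        return _ARM_CLASS[arm]
    except KeyError:
        raise NormativeError(f"unknown arm role {arm!r}") from None


def score_label(task: str, arm: str) -> str:
    """Reporting label for a task score unit, e.g. VGR-D, RVGR-A, BOB."""
    if arm == "bimanual":
        return task
    return f"{task}-{_ARM_SUFFIX[arm]}"


def model_label(task: str, arm: str) -> str:
    """Change-model key: reporting label with patient arms mapped to their
    control arm class (affected -> ND slot, unaffected -> D slot)."""
    cls = arm_class(arm)
    return task if cls == "bimanual" else f"{task}-{_ARM_SUFFIX[cls]}"


@dataclass
class ChangeEntry:
    """Control difference distribution and thresholds for one task score."""

    label: str
    mean_diff: float
    sd_diff: float
    sc: float
    le: float
    le_significant: bool
    n: int = 0

    def __post_init__(self) -> None:
        if self.sd_diff <= 0:
            raise NormativeError(f"{self.label}: difference SD must be positive")
        if self.sc < 0:
            raise NormativeError(f"{self.label}: SC threshold must be non-negative")
        if not self.le_significant and self.le != 0:
            raise NormativeError(f"{self.label}: LE must be 0 unless flagged significant")


@dataclass
class ChangeModel:
    entries: dict[str, ChangeEntry] = field(default_factory=dict)

    def __getitem__(self, label: str) -> ChangeEntry:
        if label not in self.entries:
            raise NormativeError(f"no change model for task score {label!r}")
        return self.entries[label]

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: asdict(v) for k, v in sorted(self.entries.items())}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ChangeModel":
        with open(path) as fh:
            return cls({k: ChangeEntry(**v) for k, v in json.load(fh).items()})


def fit_change_model(
    control_scores: pd.DataFrame,
    le_table: dict[str, float] | None = DEFAULT_LEARNING_EFFECTS,
    alpha: float = 0.05,
    sc_multiplier: float = SC_MULTIPLIER,
    min_paired: int = MIN_PAIRED_CONTROLS,
    unpaired: str = "error",
) -> ChangeModel:
    """Estimate difference distributions from twice-assessed controls.

    Parameters
    ----------
    control_scores
        Scored control table (columns including ``participant_id, visit, task,
        arm, z_task_score``) containing exactly two visits per participant.
    le_table
        Fixed learning effects keyed by score label; entries present here
        override the paired-t estimate.  Pass ``None`` to estimate everything.
    unpaired
        ``'error'`` (default) refuses participants missing one of the two
        assessments of a task score; ``'drop'`` excludes them from that task.
    """
    if unpaired not in ("error", "drop"):
        raise NormativeError(f"unpaired must be 'error' or 'drop', got {unpaired!r}")
    df = control_scores.copy()
    visits = sorted(df["visit"].unique(), key=_visit_order)
    if len(visits) != 2:
        raise NormativeError(
            f"change model needs exactly two visits, got {visits!r}"
        )
    first, last = visits
    df["label"] = [model_label(t, a) for t, a in zip(df["task"], df["arm"])]

    entries: dict[str, ChangeEntry] = {}
    for label, grp in df.groupby("label", sort=True):
        wide = grp.pivot_table(
            index="participant_id", columns="visit", values="z_task_score", aggfunc="first"
        )
        incomplete = sorted(wide.index[wide.isna().any(axis=1)])
        if incomplete:
            if unpaired == "error":
                raise NormativeError(
                    f"{label}: participants without both assessments: {incomplete}"
                )
            wide = wide.dropna()
        diffs = (wide[last] - wide[first]).to_numpy(dtype=float)
        if len(diffs) < min_paired:
            raise NormativeError(
                f"{label}: only {len(diffs)} paired controls (need >= {min_paired})"
            )
        sd = float(np.std(diffs, ddof=1))
        if sd <= 1e-12:
            raise NormativeError(f"{label}: degenerate (zero-SD) control differences")
        mean = float(np.mean(diffs))
        if le_table is not None and label in le_table:
            le, le_sig = float(le_table[label]), True
        else:
            p_paired = float(stats.ttest_1samp(diffs, 0.0).pvalue)
            le_sig = p_paired < alpha
            le = mean if le_sig else 0.0
        entries[label] = ChangeEntry(
            label=label,
            mean_diff=mean,
            sd_diff=sd,
            sc=sc_multiplier * sd,
            le=le,
            le_significant=le_sig,
            n=len(diffs),
        )
    return ChangeModel(entries)


_VISIT_ORDER = {"2wk": 0, "6wk": 1, "3mo": 2, "1yr": 3}


def _visit_order(v: str) -> int:
    return _VISIT_ORDER.get(v, 99)


def individual_change_p(delta_z: float, entry: ChangeEntry, apply_le: bool = True):
    """Folded tail probability of an observed z-difference under the control model.

    The CDF of Normal(mean_diff, sd_diff) is evaluated at the (learning-
    adjusted) difference; values above 0.5 are reported as 1 - CDF so that
    small p always means extreme in either direction.
    """
    delta = np.asarray(delta_z, dtype=float)
    if apply_le:
        delta = delta - entry.le
    # min(CDF, 1 - CDF) == sf(|standardized|): exact symmetry in both tails
    z = (delta - entry.mean_diff) / entry.sd_diff
    p = stats.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def sc_boundary(ts_first, entry: ChangeEntry) -> tuple:
    """Curved significant-change boundary in Task-Score space.

    For a first-visit Task Score the second visit is non-significant while it
    stays within ``[T(z1 - SC + LE), T(z1 + SC + LE)]``; the envelope is
    symmetric in z-space (width 2 SC) and shifted by LE.
    """
    z1 = inverse_task_score(ts_first)
    lower = task_score(np.asarray(z1) - entry.sc + entry.le)
    upper = task_score(np.asarray(z1) + entry.sc + entry.le)
    return lower, upper


def classify_change(first_ts: float, last_ts: float, entry: ChangeEntry, apply_le: bool = True):
    """Classify a first-to-last Task Score change for one participant/task.

    Returns ``(classification, delta_z, adjusted_delta, p_value)`` with
    classification in {improved, deteriorated, no_change}; boundary-exact
    changes are no_change.  ``apply_le=False`` skips the learning adjustment
    (transitions beyond the second exposure, where the one-time practice gain
    has already been realized).
    """
    z1 = inverse_task_score(first_ts)
    z2 = inverse_task_score(last_ts)
    delta = z2 - z1
    adjusted = delta - entry.le if apply_le else delta
    # boundary-exact points count as no change (1e-9 envelope tolerance)
    if adjusted < -entry.sc - _BOUNDARY_TOL:
        cls = "improved"
    elif adjusted > entry.sc + _BOUNDARY_TOL:
        cls = "deteriorated"
    else:
        cls = "no_change"
    p = individual_change_p(delta, entry, apply_le=apply_le)
    return cls, float(delta), float(adjusted), float(p)


CHANGE_COLUMNS = [
    "participant_id", "group", "task", "arm", "transition",
    "delta_z", "adjusted_delta", "p_value", "classification",
]


def evaluate_changes(
    scored: pd.DataFrame,
    model: ChangeModel,
    mode: str = "first_last",
) -> pd.DataFrame:
    """Per-participant change results from a scored longitudinal table.

    ``mode='first_last'`` compares the earliest and latest visit of each
    participant/task/arm (the two-visit analysis); ``mode='consecutive'``
    evaluates every adjacent visit pair (the multi-visit analysis).
    Participants missing either end of a transition are omitted.
    """
    if mode not in ("first_last", "consecutive"):
        raise NormativeError(f"unknown change mode {mode!r}")
    rows = []
    for (pid, group, task, arm), grp in scored.groupby(
        ["participant_id", "group", "task", "arm"], sort=True
    ):
        grp = grp.sort_values("visit", key=lambda s: s.map(_visit_order))
        visits = grp["visit"].tolist()
        ts = grp["task_score"].tolist()
        if len(visits) < 2:
            continue
        if mode == "first_last":
            pairs = [(0, len(visits) - 1)]
        else:
            pairs = [(i, i + 1) for i in range(len(visits) - 1)]
        entry = model[model_label(task, arm)]
        for i, j in pairs:
            # the one-time practice gain applies only to transitions that
            # start from the participant's first exposure
            cls, delta, adj, p = classify_change(ts[i], ts[j], entry, apply_le=(i == 0))
            rows.append(
                dict(
                    participant_id=pid, group=group, task=task, arm=arm,
                    transition=f"{visits[i]}->{visits[j]}",
                    delta_z=delta, adjusted_delta=adj, p_value=p,
                    classification=cls,
                )
            )
    return pd.DataFrame(rows, columns=CHANGE_COLUMNS)


def calibrate_multivisit_threshold(
    observed_p,
    n_sim: int = 1000,
    n_transitions: int = 3,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """FDR-calibrated p threshold for many-transition change testing.

    ``n_sim`` null p-values per transition are simulated under the folded
    reporting convention (uniform CDF value u reported as min(u, 1-u), i.e.
    uniform on (0, 0.5]), pooled with the observed p-values, and a
    Benjamini-Hochberg step-up at ``alpha`` is applied to the pooled family.
    Returns the largest rejected p (0 when nothing is rejected); observed
    transitions with p at or below it are significant.
    """
    observed = np.asarray(observed_p, dtype=float)
    if observed.size == 0:
        raise NormativeError("no observed p-values to calibrate against")
    if (observed <= 0).any() or (observed > 1).any():
        raise NormativeError("observed p-values must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n_sim * n_transitions)
    nulls = np.minimum(u, 1.0 - u)
    pooled = np.concatenate([observed, nulls])
    _, threshold = bh_adjust(pooled, alpha=alpha)
    return float(threshold)
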