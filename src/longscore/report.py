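"""Cohort-level report structures derived from scored and change data.

Emits the tabular analogues of the study deliverables: impairment-rate
tables with per-cell denominators, persistence-of-impairment counts,
participant x task change matrices with marginal fractions and summary
counts, and per-participant trajectory exports with significant-change
boundary curves.  Percentages recompute exactly from their own counts
(one decimal for rate tables, integer percent for summary fractions).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normative import NormativeError
from .change import ChangeModel, model_label, score_label, sc_boundary

__all__ = [
    "percent",
    "impairment_table",
    "persistence_counts",
    "change_matrix",
    "trajectory_export",
    "boundary_table",
    "write_run_manifest",
]

_VISIT_ORDER = {"2wk": 0, "6wk": 1, "3mo": 2, "1yr": 3}


def percent(n_events: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of ``n_events`` out of ``n_total`` at reporting precision."""
    if n_total <= 0:
        raise NormativeError("percentage denominator must be positive")
    if not 0 <= n_events <= n_total:
        raise NormativeError("event count must lie within [0, denominator]")
    value = round(100.0 * n_events / n_total, decimals)
    return value if decimals else int(value)


def _labelled(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["label"] = [score_label(t, a) for t, a in zip(out["task"], out["arm"])]
    return out


def impairment_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Impaired/assessed counts per (group, task score, visit).

    Cells with nobody assessed are simply absent (missing, not 0%); the
    denominators vary per cell as participants miss tasks or visits.
    """
    df = _labelled(scored)
    out = (
        df.groupby(["group", "label", "visit"], sort=True)["impaired"]
        .agg(n_impaired="sum", n_assessed="size")
        .reset_index()
    )
    out["n_impaired"] = out["n_impaired"].astype(int)
    out["percent"] = [
        percent(k, n) for k, n in zip(out["n_impaired"], out["n_assessed"])
    ]
    out = out.sort_values(
        ["group", "label", "visit"],
        key=lambda s: s.map(_VISIT_ORDER) if s.name == "visit" else s,
    ).reset_index(drop=True)
    return out


def persistence_counts(
    scored: pd.DataFrame,
    first: str | None = None,
    last: str | None = None,
) -> pd.DataFrame:
    """Participants impaired at both the first and last assessment.

    Denominator: assessed at both visits.  A participant counts as persistent
    only when flagged impaired at both.
    """
    df = _labelled(scored)
    rows = []
    for (group, label), grp in df.groupby(["group", "label"], sort=True):
        visits = sorted(grp["visit"].unique(), key=_VISIT_ORDER.get)
        v_first = first or visits[0]
        v_last = last or visits[-1]
        if v_first == v_last:
            continue
        wide = grp.pivot_table(
            index="participant_id", columns="visit", values="impaired", aggfunc="first"
        )
        if v_first not in wide.columns or v_last not in wide.columns:
            continue
        both = wide[[v_first, v_last]].dropna()
        n_both = len(both)
        if n_both == 0:
            continue
        n_persistent = int((both[v_first].astype(bool) & both[v_last].astype(bool)).sum())
        rows.append(
            dict(group=group, label=label, first_visit=v_first, last_visit=v_last,
                 n_persistent=n_persistent, n_assessed_both=n_both,
                 percent=percent(n_persistent, n_both))
        )
    return pd.DataFrame(
        rows,
        columns=["group", "label", "first_visit", "last_visit",
                 "n_persistent", "n_assessed_both", "percent"],
    )


@dataclass
class ChangeMatrixResult:
    """Participant x task change grid plus its marginal and summary counts."""

    matrix: pd.DataFrame          # participants x labels, entries in
                                  # {improved, deteriorated, no_change, missing}
    marginals: pd.DataFrame       # per label: fractions improved/deteriorated
    summary: dict                 # cohort-level counts and integer percents


def change_matrix(change_results: pd.DataFrame) -> ChangeMatrixResult:
    """Summarize first-vs-last change classifications across the cohort.

    Total assessments counts every participant x task-score cell of the grid
    (missing cells included), so a cohort of 28 with 10 task scores
    contributes 280.
    """
    if change_results.empty:
        raise NormativeError("no change results to summarize")
    df = _labelled(change_results)
    matrix = df.pivot_table(
        index="participant_id", columns="label", values="classification", aggfunc="first"
    )
    all_labels = sorted(df["label"].unique())
    matrix = matrix.reindex(columns=all_labels).fillna("missing")

    marg_rows = []
    for label in all_labels:
        col = matrix[label]
        n_eval = int((col != "missing").sum())
        marg_rows.append(
            dict(
                label=label,
                n_evaluated=n_eval,
                n_improved=int((col == "improved").sum()),
                n_deteriorated=int((col == "deteriorated").sum()),
                frac_improved=percent(int((col == "improved").sum()), n_eval, 0)
                if n_eval else np.nan,
                frac_deteriorated=percent(int((col == "deteriorated").sum()), n_eval, 0)
                if n_eval else np.nan,
            )
        )
    marginals = pd.DataFrame(marg_rows)

    changed = matrix.isin(["improved", "deteriorated"])
    n_participants = len(matrix)
    per_person = changed.sum(axis=1)
    n_changes = int(changed.to_numpy().sum())
    summary = dict(
        n_participants=n_participants,
        n_task_scores=len(all_labels),
        total_assessments=n_participants * len(all_labels),
        total_changes=n_changes,
        changed_ge1=int((per_person >= 1).sum()),
        changed_ge2=int((per_person >= 2).sum()),
        improved_ge1=int(((matrix == "improved").sum(axis=1) >= 1).sum()),
        deteriorated_ge1=int(((matrix == "deteriorated").sum(axis=1) >= 1).sum()),
    )
    summary["pct_changed_ge1"] = percent(summary["changed_ge1"], n_participants, 0)
    summary["pct_changed_ge2"] = percent(summary["changed_ge2"], n_participants, 0)
    summary["pct_improved_ge1"] = percent(summary["improved_ge1"], n_participants, 0)
    summary["pct_deteriorated_ge1"] = percent(summary["deteriorated_ge1"], n_participants, 0)
    return ChangeMatrixResult(matrix=matrix, marginals=marginals, summary=summary)


def trajectory_export(
    scored: pd.DataFrame,
    change_results: pd.DataFrame,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-participant Task Score series with per-transition significance.

    One row per participant x task score x transition, carrying the scores at
    both ends.  With ``p_threshold`` set (multi-visit FDR calibration) a
    transition is significant when its p-value is at or below it; otherwise
    the envelope classification decides.
    """
    df = _labelled(scored)
    ch = _labelled(change_results)
    score_ix = df.set_index(["participant_id", "label", "visit"])["task_score"]
    rows = []
    for r in ch.itertuples(index=False):
        v_from, v_to = r.transition.split("->")
        ts_from = float(score_ix.get((r.participant_id, r.label, v_from), np.nan))
        ts_to = float(score_ix.get((r.participant_id, r.label, v_to), np.nan))
        if p_threshold is not None:
            significant = bool(p_threshold > 0 and r.p_value <= p_threshold)
        else:
            significant = r.classification != "no_change"
        rows.append(
            dict(
                participant_id=r.participant_id, group=r.group, label=r.label,
                transition=r.transition, visit_from=v_from, visit_to=v_to,
                ts_from=ts_from, ts_to=ts_to, delta_z=r.delta_z,
                p_value=r.p_value, classification=r.classification,
                significant=significant,
            )
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["label", "participant_id", "transition"]).reset_index(drop=True)


def interval_counts(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Individuals plotted per task score and inter-visit interval."""
    return (
        trajectories.groupby(["label", "transition"], sort=True)
        .agg(n_plotted=("participant_id", "nunique"),
             n_significant=("significant", "sum"))
        .reset_index()
    )


def boundary_table(
    model: ChangeModel,
    task: str,
    arm: str,
    ts_grid=None,
) -> pd.DataFrame:
    """Significant-change boundary curves sampled on a Task-Score grid."""
    if ts_grid is None:
        ts_grid = np.linspace(0.05, 6.0, 120)
    entry = model[model_label(task, arm)]
    lower, upper = sc_boundary(np.asarray(ts_grid, dtype=float), entry)
    return pd.DataFrame(
        dict(label=score_label(task, arm), ts_first=ts_grid, lower=lower, upper=upper)
    )


def write_run_manifest(path, config: dict, seed, thresholds: dict) -> None:
    """Persist config, seed, versions and every derived threshold of a run."""
    import longscore

    manifest = dict(
        package="longscore",
        version=longscore.__version__,
        python=platform.python_version(),
        seed=seed,
        config=config,
        thresholds=thresholds,
    )
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
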