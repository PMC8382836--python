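"""Group-level hypothesis tests on Z-Task Scores with FDR control.

At each timepoint the cohort's Z-Task Scores are compared against the healthy
reference mean of 0 with one-sample Student t-tests; the same test applied to
paired first-minus-last differences asks whether the group changed on
average.  With 10 task scores x 3 contrasts (first visit, last visit,
difference) x 2 patient groups the family holds 60 p-values; the
Benjamini-Hochberg step-up controls the false discovery rate across it, and
the Bonferroni-style cut-off alpha/m is reported alongside for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .normative import NormativeError

__all__ = ["one_sample_t", "bh_adjust", "group_summary", "GROUP_SUMMARY_COLUMNS"]

EXPECTED_FAMILY_SIZE = 60

_VISIT_ORDER = {"2wk": 0, "6wk": 1, "3mo": 2, "1yr": 3}


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample Student t-test of mean == mu0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise NormativeError(f"one-sample t needs n >= 2, got n = {x.size}")
    if np.std(x, ddof=1) == 0:
        raise NormativeError("one-sample t is undefined for zero sample SD")
    res = stats.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Rejects every p at or below p_(k*) where k* is the largest k with
    p_(k) <= k * alpha / m; ties are rejected together.  Returns the boolean
    rejection flags (input order) and the rejection threshold p_(k*)
    (0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise NormativeError("empty p-value family")
    if (p <= 0).any() or (p > 1).any():
        raise NormativeError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) * alpha / m)
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    threshold = float(sorted_p[np.max(np.nonzero(below)[0])])
    return p <= threshold, threshold


GROUP_SUMMARY_COLUMNS = [
    "group", "task", "arm", "contrast", "n", "t", "p",
    "significant_fdr", "significant_bonferroni",
]


def group_summary(
    scored: pd.DataFrame,
    alpha: float = 0.05,
    groups: tuple = ("tia", "migraine"),
    expected_family: int | None = EXPECTED_FAMILY_SIZE,
) -> pd.DataFrame:
    """One-sample t-tests per group x task score x contrast, FDR over the family.

    Contrasts: ``at_first`` (earliest visit vs 0), ``at_last`` (latest visit
    vs 0) and ``difference`` (paired last minus first vs 0; participants
    contribute only when both visits are present).  Task scores with n < 2 or
    zero SD are emitted with NaN t/p and excluded from the FDR family.
    """
    rows = []
    df = scored[scored["group"].isin(groups)]
    for (group, task, arm), grp in df.groupby(["group", "task", "arm"], sort=True):
        grp = grp.sort_values("visit", key=lambda s: s.map(_VISIT_ORDER))
        first_visit = grp["visit"].iloc[0]
        last_visit = grp["visit"].iloc[-1]
        sub_first = grp[grp["visit"] == first_visit]
        sub_last = grp[grp["visit"] == last_visit]
        wide = grp.pivot_table(
            index="participant_id", columns="visit", values="z_task_score", aggfunc="first"
        )
        paired = wide.dropna(subset=[first_visit, last_visit]) if first_visit != last_visit else wide.iloc[0:0]
        for contrast, vals in (
            ("at_first", sub_first["z_task_score"].to_numpy()),
            ("at_last", sub_last["z_task_score"].to_numpy()),
            (
                "difference",
                (paired[last_visit] - paired[first_visit]).to_numpy()
                if len(paired)
                else np.empty(0),
            ),
        ):
            try:
                t, p = one_sample_t(vals)
            except NormativeError:
                t, p = np.nan, np.nan
            rows.append(
                dict(group=group, task=task, arm=arm, contrast=contrast,
                     n=len(vals), t=t, p=p)
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise NormativeError("no scored data for the requested groups")

    valid = out["p"].notna()
    m = int(valid.sum())
    if expected_family is not None and m != expected_family:
        warnings.warn(
            f"FDR family holds {m} tests, expected {expected_family}",
            stacklevel=2,
        )
    reject = np.zeros(len(out), dtype=bool)
    if m:
        flags, _ = bh_adjust(out.loc[valid, "p"].to_numpy(), alpha=alpha)
        reject[valid.to_numpy()] = flags
        bonf = np.zeros(len(out), dtype=bool)
        bonf[valid.to_numpy()] = out.loc[valid, "p"].to_numpy() < alpha / m
    else:
        bonf = reject.copy()
    out["significant_fdr"] = reject
    out["significant_bonferroni"] = bonf
    return out[GROUP_SUMMARY_COLUMNS]
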