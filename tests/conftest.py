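"""Shared fixtures: one synthetic study world fitted once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from longscore import (
    CohortConfig,
    fit_change_model,
    fit_scoring_model,
    generate_cohort,
    generate_controls,
    score_tasks,
)
from longscore.synthetic import default_parameter_specs

REFERENCE_SEED = 101


@pytest.fixture(scope="session")
def study_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def reference(study_config):
    """Reference world: control cohort, scoring model, scored controls."""
    obs, cov = generate_controls(study_config, REFERENCE_SEED)
    specs = default_parameter_specs(study_config)
    model = fit_scoring_model(obs, cov, specs)
    scored = score_tasks(obs, cov, model)
    repeat_ids = scored.groupby("participant_id")["visit"].nunique()
    repeat_scored = scored[
        scored["participant_id"].isin(repeat_ids[repeat_ids == 2].index)
    ]
    return dict(
        config=study_config,
        specs=specs,
        observations=obs,
        covariates=cov,
        model=model,
        scored=scored,
        repeat_scored=repeat_scored,
    )


@pytest.fixture(scope="session")
def change_model_estimated(reference):
    return fit_change_model(reference["repeat_scored"], le_table=None, unpaired="drop")


@pytest.fixture(scope="session")
def change_model_default(reference):
    return fit_change_model(reference["repeat_scored"], unpaired="drop")


@pytest.fixture(scope="session")
def tia_cohort(reference):
    """Scored TIA-like cohort with ground truth."""
    obs, cov, truth = generate_cohort(reference["config"], "tia", REFERENCE_SEED + 1)
    scored = score_tasks(obs, cov, reference["model"])
    return dict(observations=obs, covariates=cov, truth=truth, scored=scored)


def make_paired_scores(
    diffs: np.ndarray,
    task: str = "VGR",
    arm: str = "dominant",
    first: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Scored-table fragment with two visits whose z differences are ``diffs``."""
    n = len(diffs)
    if first is None:
        first = (rng or np.random.default_rng(0)).normal(size=n)
    pids = [f"P{i:04d}" for i in range(n)]
    rows = []
    for visit, z in (("2wk", first), ("1yr", first + diffs)):
        rows.append(
            pd.DataFrame(
                dict(participant_id=pids, group="control", visit=visit,
                     task=task, arm=arm, rss=np.nan, z_task_score=z,
                     task_score=np.nan, impaired=False)
            )
        )
    return pd.concat(rows, ignore_index=True)
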