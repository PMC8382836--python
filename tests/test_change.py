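"""Change model fitting, boundaries, classification and FDR calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from longscore import (
    ChangeEntry,
    NormativeError,
    calibrate_multivisit_threshold,
    classify_change,
    evaluate_changes,
    fit_change_model,
    individual_change_p,
    inverse_task_score,
    sc_boundary,
    task_score,
)
from longscore.change import DEFAULT_LEARNING_EFFECTS, model_label

from conftest import make_paired_scores


def entry(mean=0.0, sd=1.0, sc=None, le=0.0):
    return ChangeEntry(
        label="X", mean_diff=mean, sd_diff=sd,
        sc=1.96 * sd if sc is None else sc,
        le=le, le_significant=le != 0,
    )


class TestFitChangeModel:
    def test_sc_estimate_matches_true_scale(self):
        """Differences with SD 0.8 give SC within 10% of 1.96 x 0.8 = 1.568."""
        rng = np.random.default_rng(20)
        scored = make_paired_scores(rng.normal(0.0, 0.8, size=200), rng=rng)
        model = fit_change_model(scored, le_table=None)
        e = model["VGR-D"]
        assert e.sc == pytest.approx(1.568, rel=0.10)

    def test_injected_learning_effect_is_recovered(self):
        """A true LE of -0.72 is detected and estimated within 0.15 in at
        least 90 of 100 replicates at n = 200."""
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(100):
            scored = make_paired_scores(rng.normal(-0.72, 0.8, size=200), rng=rng)
            e = fit_change_model(scored, le_table=None)["VGR-D"]
            hits += e.le_significant and abs(e.le - (-0.72)) <= 0.15
        assert hits >= 90

    def test_fixed_table_overrides_estimation(self):
        rng = np.random.default_rng(22)
        scored = make_paired_scores(rng.normal(0.0, 0.8, size=100),
                                    task="RVGR", arm="dominant", rng=rng)
        model = fit_change_model(scored)
        assert model["RVGR-D"].le == DEFAULT_LEARNING_EFFECTS["RVGR-D"] == -0.72
        assert model["RVGR-D"].le_significant

    def test_zero_noise_repeats_are_degenerate(self):
        scored = make_paired_scores(np.zeros(50))
        with pytest.raises(NormativeError, match="zero-SD"):
            fit_change_model(scored, le_table=None)

    def test_unpaired_participants_are_reported(self):
        scored = make_paired_scores(np.random.default_rng(1).normal(size=40))
        broken = scored.drop(scored[(scored.participant_id == "P0002")
                                    & (scored.visit == "1yr")].index)
        with pytest.raises(NormativeError, match="P0002"):
            fit_change_model(broken, le_table=None)

    def test_too_few_pairs(self):
        scored = make_paired_scores(np.random.default_rng(2).normal(size=10))
        with pytest.raises(NormativeError, match="paired controls"):
            fit_change_model(scored, le_table=None)


class TestIndividualChangeP:
    def test_worked_tail_examples(self):
        """Under a N(0,1) difference model both -1.96 and +1.96 report ~0.025;
        the raw CDF at +1.96 is ~0.975 before folding."""
        e = entry()
        assert individual_change_p(-1.96, e) == pytest.approx(0.025, abs=5e-4)
        assert individual_change_p(+1.96, e) == pytest.approx(0.025, abs=5e-4)
        assert 1 - individual_change_p(+1.96, e) == pytest.approx(0.975, abs=5e-4)

    def test_model_mean_reports_half(self):
        assert individual_change_p(0.0, entry()) == 0.5

    @settings(max_examples=50, deadline=None)
    @given(d=st.floats(-10, 10), mean=st.floats(-2, 2))
    def test_symmetry_about_model_mean(self, d, mean):
        e = entry(mean=mean)
        assert individual_change_p(mean + d, e, apply_le=False) == pytest.approx(
            individual_change_p(mean - d, e, apply_le=False), rel=1e-9, abs=1e-300
        )

    def test_learning_adjustment_shifts_argument(self):
        e = entry(le=-0.5)
        assert individual_change_p(-0.5, e, apply_le=True) == pytest.approx(
            individual_change_p(0.0, e, apply_le=False)
        )


class TestScBoundary:
    def test_boundary_at_reference_median(self):
        lo, hi = sc_boundary(task_score(0.0), entry(sc=0.5))
        assert lo == pytest.approx(task_score(-0.5), abs=1e-9)
        assert hi == pytest.approx(task_score(0.5), abs=1e-9)
        assert (lo, hi) == (pytest.approx(0.3969, abs=5e-4), pytest.approx(1.0187, abs=5e-4))

    def test_zero_sc_collapses_envelope(self):
        lo, hi = sc_boundary(0.6745, entry(sc=0.0))
        assert lo == pytest.approx(0.6745) == hi

    def test_learning_effect_shifts_boundary(self):
        lo, hi = sc_boundary(task_score(0.0), entry(sc=0.5, le=-0.5))
        assert lo == pytest.approx(task_score(-1.0), abs=1e-9)
        assert hi == pytest.approx(task_score(0.0), abs=1e-9)
        assert hi == pytest.approx(0.6745, abs=5e-4)

    def test_boundary_width_grows_away_from_zero(self):
        """Curvature: the Task-Score envelope is wider at TS 2.5 than at the
        reference median — far-from-0 scores must change more."""
        e = entry(sc=0.5)
        w_mid = np.subtract(*sc_boundary(0.6745, e)[::-1])
        w_far = np.subtract(*sc_boundary(2.5, e)[::-1])
        assert w_far > w_mid

    def test_symmetric_in_z_without_le_asymmetric_with(self):
        ts0 = 1.2
        z0 = inverse_task_score(ts0)
        lo, hi = sc_boundary(ts0, entry(sc=0.7))
        assert z0 - inverse_task_score(lo) == pytest.approx(
            inverse_task_score(hi) - z0, abs=1e-9
        )
        lo2, hi2 = sc_boundary(ts0, entry(sc=0.7, le=-0.3))
        assert z0 - inverse_task_score(lo2) != pytest.approx(
            inverse_task_score(hi2) - z0, abs=1e-6
        )

    def test_rejects_non_positive_start(self):
        with pytest.raises(NormativeError):
            sc_boundary(0.0, entry())


class TestClassifyChange:
    def test_no_change_for_identical_scores(self):
        cls, delta, adj, p = classify_change(1.3, 1.3, entry())
        assert cls == "no_change" and delta == 0.0

    def test_agrees_with_boundary(self):
        """last outside [lower, upper] if and only if classified as change;
        boundary-exact points are no_change."""
        e = entry(sc=0.8, le=-0.3)
        rng = np.random.default_rng(30)
        firsts = task_score(rng.normal(size=300))
        lasts = task_score(rng.normal(size=300))
        for f, l in zip(firsts, lasts):
            lo, hi = sc_boundary(f, e)
            cls = classify_change(f, l, e)[0]
            assert (cls != "no_change") == bool(l < lo - 1e-9 or l > hi + 1e-9)
        # exactly on the boundary
        lo, hi = sc_boundary(1.0, e)
        assert classify_change(1.0, lo, e)[0] == "no_change"
        assert classify_change(1.0, hi, e)[0] == "no_change"

    def test_null_flag_rate_is_five_percent(self):
        """With a correct model and no true change, ~5% of pairs are flagged."""
        rng = np.random.default_rng(31)
        sd = 0.8
        z1 = rng.normal(size=10**4)
        delta = rng.normal(0, sd, size=10**4)
        e = entry(sd=sd)
        flagged = np.abs(delta) > e.sc
        # classify_change agrees with the direct envelope on every pair
        sample = rng.choice(10**4, size=200, replace=False)
        for i in sample:
            cls = classify_change(task_score(z1[i]), task_score(z1[i] + delta[i]), e)[0]
            assert (cls != "no_change") == flagged[i]
        assert flagged.mean() == pytest.approx(0.05, abs=0.007)

    def test_sensitivity_and_false_flags_with_true_deterioration(self):
        """20% true deteriorations of 2.5 SD: sensitivity >= 60% and false
        flags among nulls <= 7%, pooled over 100 seeded replicates."""
        sd = 0.8
        e = entry(sd=sd)
        hits = trials = false_flags = nulls = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            true_det = rng.uniform(size=100) < 0.2
            delta = rng.normal(0, sd, size=100) + 2.5 * sd * true_det
            flagged_det = delta > e.sc
            flagged_any = np.abs(delta) > e.sc
            hits += int(flagged_det[true_det].sum())
            trials += int(true_det.sum())
            false_flags += int(flagged_any[~true_det].sum())
            nulls += int((~true_det).sum())
        assert hits / trials >= 0.60
        assert false_flags / nulls <= 0.07


class TestEvaluateChanges:
    def test_learning_applies_only_to_first_transition(self, change_model_default, reference):
        """In consecutive mode the LE adjustment is used for the first
        transition only; later transitions compare raw differences."""
        label = "RVGR-D"
        e = change_model_default[label]
        z = [0.0, -0.7, -0.6, -0.5]
        visits = ["2wk", "6wk", "3mo", "1yr"]
        scored = pd.DataFrame(
            dict(participant_id="T0", group="tia", visit=visits, task="RVGR",
                 arm="unaffected", rss=np.nan, z_task_score=z,
                 task_score=task_score(np.array(z)), impaired=False)
        )
        res = evaluate_changes(scored, change_model_default, mode="consecutive")
        assert len(res) == 3
        first = res[res.transition == "2wk->6wk"].iloc[0]
        later = res[res.transition == "6wk->3mo"].iloc[0]
        assert first["adjusted_delta"] == pytest.approx(-0.7 - e.le)
        assert later["adjusted_delta"] == pytest.approx(0.1)

    def test_first_last_uses_extreme_visits(self, change_model_default):
        z = [0.0, 2.0, 0.0]
        scored = pd.DataFrame(
            dict(participant_id="T0", group="tia", visit=["2wk", "6wk", "1yr"],
                 task="BOB", arm="bimanual", rss=np.nan, z_task_score=z,
                 task_score=task_score(np.array(z)), impaired=False)
        )
        res = evaluate_changes(scored, change_model_default, mode="first_last")
        assert len(res) == 1
        assert res.iloc[0]["transition"] == "2wk->1yr"
        assert res.iloc[0]["delta_z"] == pytest.approx(0.0)


class TestCalibrateMultivisitThreshold:
    def test_pure_null_rejects_nothing(self):
        assert calibrate_multivisit_threshold([0.4] * 50, seed=0) == 0.0

    def test_strong_signals_against_bh_oracle(self):
        """10 observed p = 1e-8 pooled with 3000 simulated nulls reproduce the
        brute-force step-up threshold."""
        observed = np.full(10, 1e-8)
        thr = calibrate_multivisit_threshold(observed, n_sim=1000, n_transitions=3,
                                             alpha=0.05, seed=42)
        assert thr >= 1e-8
        # independent step-up oracle on the same pooled family
        rng = np.random.default_rng(42)
        u = rng.uniform(size=3000)
        pooled = np.sort(np.concatenate([observed, np.minimum(u, 1 - u)]))
        m = len(pooled)
        kstar = max((k for k in range(1, m + 1) if pooled[k - 1] <= k * 0.05 / m),
                    default=0)
        assert thr == pytest.approx(pooled[kstar - 1])

    def test_deterministic_under_fixed_seed(self):
        obs = np.geomspace(1e-9, 0.5, 40)
        a = calibrate_multivisit_threshold(obs, seed=7)
        b = calibrate_multivisit_threshold(obs, seed=7)
        assert a == b

    def test_empty_observed_errors(self):
        with pytest.raises(NormativeError):
            calibrate_multivisit_threshold([], seed=0)


def test_model_label_pairs_patient_and_control_arms():
    assert model_label("VGR", "unaffected") == "VGR-D"
    assert model_label("VGR", "affected") == "VGR-ND"
    assert model_label("BOB", "bimanual") == "BOB"
    assert model_label("RVGR", "dominant") == "RVGR-D"
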