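"""Pipeline: baselines, expected directions, error scoring, effects, report."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from egopoint.analysis import (
    PointingStudy,
    compute_baseline,
    compute_errors,
    condition_effect,
    correlate_selfreport,
    expected_direction,
    summarize,
    target_summaries,
)
from egopoint.circgeo import circ_distance
from egopoint.session_model import DirectionAngles, RoomLayout
from egopoint.simulate import SimConfig, simulate_cohort, simulate_session


@pytest.fixture(scope="module")
def noiseless_sessions():
    config = SimConfig(n_participants=2, seed=0, azimuth_sd_deg=0.0,
                       elevation_sd_deg=0.0, participant_bias_sd_deg=0.0,
                       mr_flip_prob=0.0)
    sessions, _ = simulate_cohort(config)
    return config, sessions


class TestBaseline:
    def test_noiseless_baseline_equals_true_directions(self, noiseless_sessions):
        config, sessions = noiseless_sessions
        baselines = compute_baseline(sessions)
        roster = {t.name: t for t in config.roster}
        for pid, per_target in baselines.per_participant.items():
            for name, d in per_target.items():
                true = roster[name].true_direction
                assert d.elevation_deg == pytest.approx(true.elevation_deg,
                                                        abs=1e-9)
                if true.azimuth_defined:
                    assert abs(circ_distance(d.azimuth_deg,
                                             true.azimuth_deg)) < 1e-9
                else:
                    assert not d.azimuth_defined

    def test_insufficient_coverage_reported_not_fatal(self, noiseless_sessions):
        _, sessions = noiseless_sessions
        day2_only = [s for s in sessions if s.day == 2]
        # drop all but one EO trial of one target for one participant
        import copy
        s = copy.deepcopy(day2_only[0])
        victim = s.trials[0].target_name
        kept = [t for t in s.trials if not (t.condition == "EO"
                                            and t.target_name == victim)]
        kept.append([t for t in s.trials if t.condition == "EO"
                     and t.target_name == victim][0])
        s.trials = sorted(kept, key=lambda t: t.presentation_index)
        baselines = compute_baseline([s])
        assert any(victim in msg for msg in baselines.coverage)
        assert victim not in baselines.per_participant[s.participant_id]


class TestExpectedDirection:
    def test_mr_imagined_right_shifts_minus_90(self):
        base = DirectionAngles(30.0, 10.0)
        exp = expected_direction(base, "MR", "right")
        assert exp.azimuth_deg == pytest.approx(-60.0)
        assert exp.elevation_deg == pytest.approx(10.0)

    def test_mr_imagined_left_shifts_plus_90(self):
        exp = expected_direction(DirectionAngles(30.0, 0.0), "MR", "left")
        assert exp.azimuth_deg == pytest.approx(120.0)

    def test_real_rotation_leaves_world_direction_fixed(self):
        base = DirectionAngles(30.0, 5.0)
        assert expected_direction(base, "RR", "left") == base

    def test_unshifted_mode_returns_baseline(self):
        base = DirectionAngles(30.0, 5.0)
        assert expected_direction(base, "MR", "right",
                                  apply_mr_transform=False) == base

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            expected_direction(DirectionAngles(0, 0), "XX", "left")


class TestComputeErrors:
    def test_noiseless_trials_have_zero_error(self, noiseless_sessions):
        _, sessions = noiseless_sessions
        baselines = compute_baseline(sessions)
        errors = compute_errors(sessions, baselines)
        az = errors["azimuth_error"].dropna()
        assert np.abs(az).max() < 1e-9
        assert np.abs(errors["elevation_error"]).max() < 1e-9
        assert errors["total_angle_error"].max() < 1e-9

    def test_wraparound_error_sign(self):
        # trial at azimuth 10, expected at 350 (=-10): error is +20
        assert float(circ_distance(10.0, -10.0)) == pytest.approx(20.0)

    def test_mr_without_transform_concentrates_at_90(self, noiseless_sessions):
        _, sessions = noiseless_sessions
        baselines = compute_baseline(sessions)
        errors = compute_errors(sessions, baselines, mr_transform=False)
        mr = errors[(errors.condition == "MR")].dropna(subset=["azimuth_error"])
        assert np.all(np.isclose(np.abs(mr["azimuth_error"]), 90.0, atol=1e-9))

    def test_scoring_equivariant_under_world_rotation(self):
        cfg1 = SimConfig(n_participants=2, seed=5)
        layout_rot = RoomLayout(facing_heading_deg=137.0)
        cfg2 = SimConfig(n_participants=2, seed=5, layout=layout_rot)
        s1, _ = simulate_cohort(cfg1)
        s2, _ = simulate_cohort(cfg2)
        e1 = compute_errors(s1, compute_baseline(s1))
        e2 = compute_errors(s2, compute_baseline(s2))
        np.testing.assert_allclose(e1["azimuth_error"], e2["azimuth_error"],
                                   atol=1e-7)
        np.testing.assert_allclose(e1["elevation_error"], e2["elevation_error"],
                                   atol=1e-7)

    def test_straight_up_scored_in_elevation_only(self, noiseless_sessions):
        _, sessions = noiseless_sessions
        baselines = compute_baseline(sessions)
        errors = compute_errors(sessions, baselines)
        up = errors[errors.target == "ceiling_above"]
        assert up["azimuth_error"].isna().all()
        assert np.isfinite(up["elevation_error"]).all()


class TestSummaries:
    def test_zero_errors_summarize_to_zero(self, noiseless_sessions):
        _, sessions = noiseless_sessions
        baselines = compute_baseline(sessions)
        errors = compute_errors(sessions, baselines)
        summ = summarize(errors, by=("condition",))
        assert np.allclose(summ["mean_abs_azimuth_error"], 0.0, atol=1e-9)
        assert np.allclose(summ["azimuth_sd"].fillna(0.0), 0.0, atol=1e-9)

    def test_condition_sd_ordering(self, small_cohort):
        _, sessions, _ = small_cohort
        errors = compute_errors(sessions, compute_baseline(sessions))
        summ = summarize(errors, by=("condition",)).set_index("condition")
        sds = summ["azimuth_sd"]
        assert sds["EO"] < sds["EC"] < sds["RR"] < sds["MR"]

    def test_contralateral_annotation(self, small_cohort):
        _, sessions, _ = small_cohort
        errors = compute_errors(sessions, compute_baseline(sessions))
        summ = summarize(errors, by=("participant_id", "condition", "target"))
        marked = summ[summ["contralateral"]]
        # right-handers have their eccentric-left targets annotated
        assert set(marked["target"]) <= {"left_floor_corner", "left_wall_shelf",
                                         "left_ceiling_lamp", "left_door_handle",
                                         "right_waste_bin", "right_light_switch",
                                         "right_smoke_detector", "right_monitor"}
        assert len(marked)

    def test_excluding_eccentric_targets_shrinks_az_el_ratio(self, small_cohort):
        _, sessions, _ = small_cohort
        errors = compute_errors(sessions, compute_baseline(sessions))
        eo = errors[errors.condition == "EO"]
        full = summarize(eo, by=("condition",)).iloc[0]
        central = summarize(eo[np.abs(eo["target_azimuth"]) <= 60.0],
                            by=("condition",)).iloc[0]
        ratio_full = full["azimuth_sd"] / full["elevation_sd"]
        ratio_central = central["azimuth_sd"] / central["elevation_sd"]
        assert ratio_central < ratio_full

    def test_target_summaries_counts(self, small_cohort):
        _, sessions, _ = small_cohort
        tsum = target_summaries(sessions)
        eo = tsum[tsum.condition == "EO"]
        # 8 reps day 1 + 6 reps day 2 pooled per participant
        assert set(eo["n_trials"]) == {14}


class TestConditionEffect:
    def test_two_conditions_f_equals_paired_t_squared(self, rng):
        x = pd.DataFrame({"EO": rng.normal(0, 1, 12),
                          "EC": rng.normal(0.5, 1, 12)})
        eff = condition_effect(x, n_perm=99, seed=0)
        from scipy import stats
        t, _ = stats.ttest_rel(x["EC"], x["EO"])
        assert eff.f_value == pytest.approx(t ** 2, abs=1e-8)

    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM
        x = pd.DataFrame(rng.normal(0, 1, (10, 4)), columns=list("ABCD"))
        eff = condition_effect(x, n_perm=99, seed=0)
        long = x.reset_index().melt(id_vars="index", var_name="cond",
                                    value_name="y")
        res = AnovaRM(long, "y", "index", within=["cond"]).fit()
        f_sm = float(res.anova_table["F Value"].iloc[0])
        p_sm = float(res.anova_table["Pr > F"].iloc[0])
        assert eff.f_value == pytest.approx(f_sm, abs=1e-8)
        assert eff.p_parametric == pytest.approx(p_sm, abs=1e-8)

    def test_strong_effect_detected_by_permutation(self, rng):
        base = rng.normal(10, 1, (20, 3))
        x = pd.DataFrame(base, columns=["EO", "EC", "RR"])
        x["RR"] += 5.0
        eff = condition_effect(x, n_perm=1999, seed=1)
        assert eff.p_permutation <= 0.001

    def test_incomplete_cells_rejected(self, rng):
        x = pd.DataFrame(rng.normal(0, 1, (5, 3)))
        x.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            condition_effect(x)

    def test_df_reporting(self, rng):
        x = pd.DataFrame(rng.normal(0, 1, (8, 4)))
        eff = condition_effect(x, n_perm=19, seed=0)
        assert (eff.df_between, eff.df_within) == (3, 21)


class TestCorrelations:
    def test_perfect_negative_linear_relation(self):
        m = pd.DataFrame({"participant_id": list("abcdef"),
                          "err": [1.0, 2, 3, 4, 5, 6]})
        s = pd.DataFrame({"participant_id": list("abcdef"),
                          "sbsod": [-2.0, -4, -6, -8, -10, -12]})
        out = correlate_selfreport(m, s, [("err", "sbsod")])
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_recovers_population_correlation(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        y = 0.6 * x + rng.normal(0, math.sqrt(1 - 0.36), n)
        m = pd.DataFrame({"participant_id": np.arange(n), "x": x})
        s = pd.DataFrame({"participant_id": np.arange(n), "y": y})
        out = correlate_selfreport(m, s, [("x", "y")])
        assert out["r"].iloc[0] == pytest.approx(0.6, abs=0.1)

    def test_null_correlations_rarely_large(self, rng):
        n, reps = 100, 1000
        x = rng.normal(0, 1, (reps, n))
        y = rng.normal(0, 1, (reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc ** 2).sum(axis=1)
                                            * (yc ** 2).sum(axis=1))
        assert np.mean(np.abs(r) < 0.3) >= 0.95

    def test_zero_variance_flagged_undefined(self):
        m = pd.DataFrame({"participant_id": list("abcde"),
                          "err": [1.0, 1, 1, 1, 1]})
        s = pd.DataFrame({"participant_id": list("abcde"),
                          "sbsod": [1.0, 2, 3, 4, 5]})
        out = correlate_selfreport(m, s, [("err", "sbsod")])
        assert bool(out["undefined"].iloc[0])

    def test_missing_participants_dropped_pairwise(self):
        m = pd.DataFrame({"participant_id": list("abcdef"),
                          "err": [1.0, 2, 3, 4, 5, 6]})
        s = pd.DataFrame({"participant_id": list("abcd"),
                          "sbsod": [4.0, 3, 2, 1]})
        out = correlate_selfreport(m, s, [("err", "sbsod")])
        assert int(out["n"].iloc[0]) == 4


class TestModelResults:
    def test_fit_produces_summary_and_report(self, small_cohort, tmp_path, rng):
        _, sessions, _ = small_cohort
        pids = sorted({s.participant_id for s in sessions})
        scores = pd.DataFrame({
            "participant_id": pids,
            "sbsod": rng.normal(4, 1, len(pids)),
            "perspective_taking": rng.normal(20, 5, len(pids)),
            "wayfinding": rng.normal(3, 1, len(pids)),
            "spatial_anxiety": rng.normal(2, 1, len(pids)),
        })
        study = PointingStudy(sessions, scores=scores)
        results = study.fit(n_perm=199, seed=0)
        text = results.summary()
        assert "rm-ANOVA" in text and "Reliability" in text
        assert results.reliability["internal_azimuth"].estimate > 0
        manifest = results.save_report(tmp_path / "bundle", figures=False)
        names = {a["path"] for a in manifest["artifacts"]}
        assert {"errors.csv", "summary.json", "condition_summary.csv",
                "correlations.csv"} <= names
        loaded = json.loads((tmp_path / "bundle" / "summary.json").read_text())
        assert loaded["condition_effect"]["f_value"] == pytest.approx(
            results.condition_effect.f_value)
        assert "figures (disabled)" in manifest["skipped"]

    def test_missing_scores_skips_correlations(self, small_cohort, tmp_path):
        _, sessions, _ = small_cohort
        results = PointingStudy(sessions).fit(n_perm=99, seed=0)
        assert results.correlations is None
        manifest = results.save_report(tmp_path / "b", figures=False)
        assert any("correlations" in s for s in manifest["skipped"])

    def test_test_retest_reliability_high_on_simulated_cohort(self, small_cohort):
        _, sessions, _ = small_cohort
        results = PointingStudy(sessions).fit(n_perm=99, seed=0)
        assert results.reliability["test_retest_azimuth"].estimate > 0.95
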