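import numpy as np
import pandas as pd
import pytest

from causalpaf import (
    SurveyConfig,
    chapter_summary,
    demo_landscape,
    demo_roles,
    derive_first_incidence,
    fdr_select,
    joint_inclusion,
    min_case_filter,
    rank_and_tier,
    run_survey,
    sensitivity_rerun,
    simulate_landscape,
)


@pytest.fixture
def tiny_tables():
    subjects = pd.DataFrame(
        {
            "subject_id": [0, 1, 2, 3],
            "sex": ["F", "F", "M", "M"],
            "entry_age": [50.0, 50.0, 50.0, 50.0],
        }
    )
    events = pd.DataFrame(
        {
            "subject_id": [0, 0, 1, 2, 3],
            "code": ["J40", "J41", "J40", "J40", "C20"],
            "chapter": ["X", "X", "X", "X", "II"],
            "diagnosis_age": [55.0, 60.0, 45.0, 62.0, 48.0],
        }
    )
    return subjects, events


class TestDeriveFirstIncidence:
    def test_earliest_chapter_diagnosis_defines_event(self, tiny_tables):
        subjects, events = tiny_tables
        out = derive_first_incidence(subjects, events, "J40", SurveyConfig(min_cases=1))
        row = out[out["subject_id"] == 0].iloc[0]
        assert row["event"] == 1 and row["exit_age"] == 55.0

    def test_onset_before_entry_excluded(self, tiny_tables):
        subjects, events = tiny_tables
        out = derive_first_incidence(subjects, events, "J40", SurveyConfig(min_cases=1))
        assert 1 not in out["subject_id"].to_numpy()  # diagnosed at 45, entered at 50

    def test_prior_cancer_excluded(self, tiny_tables):
        subjects, events = tiny_tables
        out = derive_first_incidence(subjects, events, "J40", SurveyConfig(min_cases=1))
        assert 3 not in out["subject_id"].to_numpy()  # C20 at 48 before entry at 50

    def test_non_melanoma_skin_cancer_exempt(self, tiny_tables):
        subjects, events = tiny_tables
        events = events.copy()
        events.loc[events["code"] == "C20", "code"] = "C44"
        out = derive_first_incidence(subjects, events, "J40", SurveyConfig(min_cases=1))
        assert 3 in out["subject_id"].to_numpy()

    def test_other_code_chapter_first_censors(self):
        subjects = pd.DataFrame(
            {"subject_id": [0], "sex": ["F"], "entry_age": [50.0]}
        )
        events = pd.DataFrame(
            {
                "subject_id": [0, 0],
                "code": ["J41", "J40"],
                "chapter": ["X", "X"],
                "diagnosis_age": [55.0, 60.0],
            }
        )
        out = derive_first_incidence(subjects, events, "J40", SurveyConfig(min_cases=1))
        row = out.iloc[0]
        assert row["event"] == 0 and row["exit_age"] == 55.0

    def test_post_entry_cancer_censors_followup(self):
        subjects = pd.DataFrame({"subject_id": [0], "sex": ["F"], "entry_age": [50.0]})
        events = pd.DataFrame(
            {
                "subject_id": [0, 0],
                "code": ["C20", "J40"],
                "chapter": ["II", "X"],
                "diagnosis_age": [60.0, 70.0],
            }
        )
        out = derive_first_incidence(subjects, events, "J40", SurveyConfig(min_cases=1))
        row = out.iloc[0]
        assert row["event"] == 0 and row["exit_age"] == 60.0

    def test_death_precedence_over_tied_event(self):
        subjects = pd.DataFrame(
            {"subject_id": [0], "sex": ["F"], "entry_age": [50.0], "death_age": [60.0]}
        )
        events = pd.DataFrame(
            {
                "subject_id": [0],
                "code": ["J40"],
                "chapter": ["X"],
                "diagnosis_age": [60.0],
            }
        )
        out = derive_first_incidence(subjects, events, "J40", SurveyConfig(min_cases=1))
        assert out.iloc[0]["event"] == 0  # death wins the tie

    def test_unknown_code_rejected(self, tiny_tables):
        subjects, events = tiny_tables
        with pytest.raises(ValueError, match="unknown code"):
            derive_first_incidence(subjects, events, "Z99", SurveyConfig(min_cases=1))


class TestMinCaseFilter:
    def test_boundary(self):
        records = pd.DataFrame({"n_cases": [139, 140, 500]})
        kept = min_case_filter(records, 140)
        assert kept["n_cases"].tolist() == [140, 500]

    def test_threshold_one_keeps_all(self):
        records = pd.DataFrame({"n_cases": [1, 5]})
        assert len(min_case_filter(records, 1)) == 2

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            min_case_filter(pd.DataFrame({"n_cases": [10]}), 0)


class TestFDR:
    def test_hand_executed_step_up(self):
        mask, q = fdr_select([0.001, 0.01, 0.02, 0.04, 0.2], 0.05)
        assert mask.tolist() == [True, True, True, True, False]
        assert np.all(np.diff(q[np.argsort([0.001, 0.01, 0.02, 0.04, 0.2])]) >= 0)

    def test_all_ones_selects_none(self):
        mask, _ = fdr_select(np.ones(6), 0.05)
        assert not mask.any()

    def test_single_test_reduces_to_level(self):
        assert fdr_select([0.04], 0.05)[0].tolist() == [True]
        assert fdr_select([0.06], 0.05)[0].tolist() == [False]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_select([0.1, 1.2], 0.05)

    def test_selection_monotone_in_level(self):
        rng = np.random.default_rng(50)
        p = rng.random(40) ** 2
        strict, _ = fdr_select(p, 0.01)
        loose, _ = fdr_select(p, 0.10)
        assert not np.any(strict & ~loose)


class TestJointInclusion:
    def test_elementwise_or(self):
        out = joint_inclusion([True, False], [False, False])
        assert out.tolist() == [True, False]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            joint_inclusion([True], [True, False])

    def test_empty(self):
        assert joint_inclusion([], []).size == 0


class TestRankAndTier:
    def test_tier_thresholds_and_ranks(self):
        records = pd.DataFrame(
            {
                "code": ["A", "B", "C", "D", "E"],
                "af_joint": [0.55, 0.40, 0.25, 0.0, -0.29],
                "n_attributed": [100, 80, 30, 0, -50],
            }
        )
        out = rank_and_tier(records)
        assert out["tier"].tolist() == [
            ">=0.5", "0.35-0.5", "0.2-0.35", "-0.2-0.2", "<=-0.2",
        ]
        assert out["rank_af"].tolist() == [1, 2, 3, 4, 5]
        assert out.loc[out["code"] == "A", "rank_naf"].iloc[0] == 1
        assert out.loc[out["code"] == "E", "rank_naf"].iloc[0] == 3  # |−50|

    def test_ties_break_by_code(self):
        records = pd.DataFrame(
            {"code": ["B", "A"], "af_joint": [0.3, 0.3], "n_attributed": [10, 10]}
        )
        out = rank_and_tier(records)
        assert out.loc[out["code"] == "A", "rank_af"].iloc[0] == 1

    def test_every_record_gets_exactly_one_tier(self):
        rng = np.random.default_rng(51)
        records = pd.DataFrame(
            {
                "code": [f"X{i}" for i in range(50)],
                "af_joint": rng.uniform(-1, 1, 50),
                "n_attributed": rng.integers(-100, 100, 50),
            }
        )
        out = rank_and_tier(records)
        assert out["tier"].notna().all()


class TestChapterSummary:
    def test_minimum_disease_rule(self):
        records = pd.DataFrame(
            {
                "chapter": ["X"] * 4 + ["IX"] * 5,
                "af_joint": [0.3, 0.4, 0.5, 0.25] + [0.3, 0.2501, 0.5, 0.22, 0.35],
            }
        )
        out = chapter_summary(records)
        assert out["chapter"].tolist() == ["IX"]  # X has only 4 above the floor
        assert out["median_af"].iloc[0] == pytest.approx(0.3)
        assert out["n_diseases"].iloc[0] == 5

    def test_all_below_threshold_yields_empty_summary(self):
        records = pd.DataFrame({"chapter": ["X"] * 3, "af_joint": [0.1, 0.05, 0.15]})
        assert len(chapter_summary(records)) == 0


@pytest.fixture(scope="module")
def survey_inputs():
    lm = demo_landscape("null", n_outcomes=8)
    subjects, events = simulate_landscape(lm, 12_000, seed=60)
    roles, coding = demo_roles()
    config = SurveyConfig(min_cases=60)
    return subjects, events, roles, coding, config


class TestRunSurvey:
    def test_deterministic(self, survey_inputs):
        subjects, events, roles, coding, config = survey_inputs
        rec1, sum1 = run_survey(subjects, events, roles, coding, config)
        rec2, sum2 = run_survey(subjects, events, roles, coding, config)
        pd.testing.assert_frame_equal(rec1, rec2)
        pd.testing.assert_frame_equal(sum1, sum2)

    def test_affected_outcome_detected(self, survey_inputs):
        subjects, events, roles, coding, config = survey_inputs
        records, _ = run_survey(subjects, events, roles, coding, config)
        affected = records[records["code"] == "Q00"]
        assert affected["sel_smoking"].any()
        assert (affected["af_smoking"] > 0.1).all()

    def test_q_values_dominate_p_values(self, survey_inputs):
        subjects, events, roles, coding, config = survey_inputs
        records, _ = run_survey(subjects, events, roles, coding, config)
        assert (records["q_smoking"] >= records["p_smoking"] - 1e-12).all()
        assert (records["q_bmi"] >= records["p_bmi"] - 1e-12).all()

    def test_joint_equals_single_when_other_exposure_null(self, survey_inputs):
        """In the null landscape BMI has no true effect, so the joint
        smoking+BMI fraction tracks the smoking-only fraction."""
        subjects, events, roles, coding, config = survey_inputs
        records, _ = run_survey(subjects, events, roles, coding, config)
        affected = records[records["code"] == "Q00"]
        diff = affected["af_joint"] - affected["af_smoking"]
        # per-stratum gap is driven by the null BMI coefficients' sampling
        # noise (a few hundred cases per sex); the sex-averaged gap is tighter
        assert diff.abs().max() < 0.2
        assert abs(diff.mean()) < 0.1


class TestSensitivity:
    def test_identical_configs_give_zero_differences(self):
        lm = demo_landscape("null", n_outcomes=4)
        subjects, events = simulate_landscape(lm, 8_000, seed=61)
        roles, coding = demo_roles()
        config = SurveyConfig(min_cases=50)
        out = sensitivity_rerun(subjects, events, roles, coding, config, config)
        assert np.allclose(out["differences"]["difference"], 0.0)
        assert out["summary"]["mean"] == pytest.approx(0.0)
        assert out["summary"]["median"] == pytest.approx(0.0)

    def test_stricter_exclusions_shift_estimates(self):
        """Prior-disease exclusion correlated with exposure shifts fractions;
        the summary reports the mean/median/SD of the shifts."""
        lm = demo_landscape("null", n_outcomes=4)
        subjects, events = simulate_landscape(lm, 8_000, seed=62)
        # add a prior cardiovascular-style diagnosis preferentially in smokers
        rng = np.random.default_rng(63)
        smokers = subjects[subjects["smoking"] == "current"]
        hit = smokers[rng.random(len(smokers)) < 0.3]
        prior = pd.DataFrame(
            {
                "subject_id": hit["subject_id"].to_numpy(),
                "code": "I21",
                "chapter": "IX*",
                "diagnosis_age": np.minimum(hit["entry_age"] - 1.0, 60.0),
            }
        )
        events2 = pd.concat([events, prior], ignore_index=True)
        roles, coding = demo_roles()
        main = SurveyConfig(min_cases=50)
        sens = SurveyConfig(min_cases=50, exclusion_prefixes=("C", "I2"))
        out = sensitivity_rerun(subjects, events2, roles, coding, main, sens)
        assert {"mean", "median", "sd"} <= set(out["summary"])
        assert len(out["differences"]) > 0
        assert out["differences"]["difference"].abs().max() > 0


def test_chapter_plot_written(tmp_path):
    from causalpaf.survey import plot_chapter_medians

    summary = pd.DataFrame(
        {"chapter": ["X", "IX"], "median_af": [0.3, 0.2], "n_diseases": [8, 5]}
    )
    out = tmp_path / "chapters.png"
    plot_chapter_medians(summary, out)
    assert out.stat().st_size > 0
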