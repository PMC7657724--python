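"""Analysis operations vs closed-form and hand-computed oracles."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from eprowatch.alert_engine import evaluate_cohort
from eprowatch.analysis_pipeline import (
    AnalysisConfig,
    FIRST_12_WEEKS,
    alert_summary,
    benefit_correlation,
    binned_average_grade,
    effect_size_class,
    grade_distribution,
    pearson_matrix,
    prevalence_by_arm,
    survey_summary,
    symptom_correlations,
)
from eprowatch.cohort_simulator import Cohort, Patient, SurveyRecord
from eprowatch.epro_core import SYMPTOMS, GradedResponse
from eprowatch.scheduler import FollowUpPlan

START = dt.date(2021, 5, 3)


def _resp(pid, week, grades):
    full = {s: 0 for s in SYMPTOMS}
    full.update(grades)
    return GradedResponse(
        patient_id=pid,
        week_index=week,
        answer_date=START + dt.timedelta(days=7 * max(week - 1, 0)),
        grades=full,
    )


def _mini_cohort(patient_grades, responses):
    """patient_grades: pid -> best_response."""
    patients = [
        Patient(pid, 60.0, "male", "lung", "IV", 0, best_response=best)
        for pid, best in patient_grades.items()
    ]
    plans = [
        FollowUpPlan(p.patient_id, START, START + dt.timedelta(days=181))
        for p in patients
    ]
    return Cohort(patients=patients, responses=responses, plans=plans)


# ----------------------------------------------------------------- Pearson


def pearson_sum_formula(x, y):
    """Independent oracle: direct product-moment sum formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def test_pearson_hand_example():
    table = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
    r = pearson_matrix(table).r
    assert r.loc["x", "y"] == pytest.approx(0.8, abs=1e-12)
    assert r.loc["x", "x"] == pytest.approx(1.0)


def test_pearson_matches_sum_formula_on_random_tables():
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(3, 40))
        table = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        matrix = pearson_matrix(table)
        for i in "abcd":
            for j in "abcd":
                expected = pearson_sum_formula(table[i].tolist(), table[j].tolist())
                assert matrix.r.loc[i, j] == pytest.approx(expected, abs=1e-12)
        assert (matrix.n == n).all().all()
        # symmetry and unit diagonal
        assert np.allclose(matrix.r, matrix.r.T)
        assert np.allclose(np.diag(matrix.r), 1.0)


def test_pearson_degenerate_cases():
    table = pd.DataFrame({"x": [1, 2, 3], "neg": [-1, -2, -3], "const": [5, 5, 5]})
    r = pearson_matrix(table).r
    assert r.loc["x", "neg"] == pytest.approx(-1.0)
    assert math.isnan(r.loc["x", "const"])  # zero variance -> undefined marker
    with pytest.raises(ValueError, match="two observations"):
        pearson_matrix(pd.DataFrame({"x": [1.0]}))


# ------------------------------------------------------------ effect sizes


@pytest.mark.parametrize(
    "r,expected",
    [
        (-0.41, "medium"),
        (0.23, "small"),
        (0.05, "negligible"),
        (0.5, "large"),
        (-0.62, "large"),
        (0.3, "medium"),
        (0.1, "small"),
        (-0.099, "negligible"),
    ],
)
def test_effect_size_classes(r, expected):
    assert effect_size_class(r) == expected


def test_effect_size_rejects_undefined():
    with pytest.raises(ValueError):
        effect_size_class(float("nan"))
    with pytest.raises(ValueError):
        effect_size_class(1.2)


# ------------------------------------------------------- grade distribution


def test_grade_distribution_toy_cases():
    zeros = [_resp("A", w, {}) for w in range(1, 5)]
    dist = grade_distribution(zeros)
    assert (dist["0"] == 100.0).all()

    graded = [_resp("A", w, {"cough": g}) for w, g in enumerate([0, 1, 2, 3], start=1)]
    dist = grade_distribution(graded)
    assert dist.loc["cough"].tolist() == [25.0, 25.0, 25.0, 25.0]
    assert dist.loc["fatigue", "0"] == 100.0
    with pytest.raises(ValueError, match="window"):
        grade_distribution(graded, AnalysisConfig(window=(20, 24)))


def test_percentages_invariant_under_record_duplication():
    responses = [_resp("A", w, {"rash": w % 3}) for w in range(1, 7)]
    base = grade_distribution(responses)
    doubled = grade_distribution(responses + responses)
    pd.testing.assert_frame_equal(base, doubled)


# ------------------------------------------------------------ alert summary


def test_alert_summary_hand_count():
    responses = [
        _resp("A", 1, {"cough": 3, "fatigue": 2}),  # alerts on two symptoms
        _resp("B", 1, {}),
        _resp("C", 1, {}),
    ]
    decisions = evaluate_cohort(responses)
    summary = alert_summary(decisions, responses, AnalysisConfig(window=(1, 1)))
    assert summary.n_questionnaires == 3
    assert summary.n_alerts == 1
    assert round(100 * summary.rate, 1) == 33.3
    assert summary.by_symptom == {"cough": 1, "fatigue": 1}

    zero = alert_summary(
        evaluate_cohort([_resp("B", 1, {})]), [_resp("B", 1, {})],
        AnalysisConfig(window=(1, 1)),
    )
    assert zero.n_alerts == 0 and zero.by_symptom == {}


def test_alert_summary_rejects_orphan_decisions():
    responses = [_resp("A", 1, {"cough": 3})]
    decisions = evaluate_cohort([_resp("A", 1, {"cough": 3}), _resp("Z", 1, {"rash": 3})])
    with pytest.raises(ValueError, match="no.*matching|matching"):
        alert_summary(decisions, responses, AnalysisConfig(window=(1, 1)))


# ------------------------------------------------------ benefit correlation


def test_benefit_correlation_sign_and_undefined_markers():
    patients = {"B1": "PR", "B2": "SD", "P1": "PD", "P2": "PD"}
    responses = []
    for pid in patients:
        for w in (1, 2):
            grades = {"itching": 2 if pid.startswith("B") else 0, "fever": 1}
            responses.append(_resp(pid, w, grades))
    cohort = _mini_cohort(patients, responses)
    bcorr = benefit_correlation(cohort, FIRST_12_WEEKS)
    assert bcorr.loc["itching", "r"] == pytest.approx(1.0)
    assert bcorr.loc["itching", "effect_class"] == "large"
    # benefit-independent constant grade: undefined, never silently zero
    assert math.isnan(bcorr.loc["fever", "r"])
    assert bcorr.loc["fever", "effect_class"] is None


def test_benefit_correlation_requires_both_classes():
    patients = {"B1": "PR", "B2": "SD"}
    responses = [_resp(pid, 1, {}) for pid in patients]
    with pytest.raises(ValueError, match="both benefit classes"):
        benefit_correlation(_mini_cohort(patients, responses), FIRST_12_WEEKS)


# ------------------------------------------------------- trajectories/prev


def test_binned_average_grade():
    patients = {"A": "PR"}
    responses = [_resp("A", w, {"itching": g}) for w, g in [(1, 0), (2, 2), (3, 1)]]
    cohort = _mini_cohort(patients, responses)
    series = binned_average_grade(cohort, "itching", "all", AnalysisConfig(window=(1, 4)))
    assert series["1-2"] == pytest.approx(1.0)  # mean of grades 0 and 2
    assert series["3-4"] == pytest.approx(1.0)
    constant = binned_average_grade(
        _mini_cohort(patients, [_resp("A", w, {"rash": 1}) for w in range(1, 5)]),
        "rash", "all", AnalysisConfig(window=(1, 4)),
    )
    assert (constant == 1.0).all()
    with pytest.raises(ValueError, match="group"):
        binned_average_grade(cohort, "itching", "responders")


def test_prevalence_toy():
    patients = {"B1": "CR", "B2": "SD", "P1": "PD"}
    responses = [
        _resp("B1", 1, {"itching": 1}),
        _resp("B2", 1, {}),
        _resp("P1", 1, {}),
    ]
    prev = prevalence_by_arm(_mini_cohort(patients, responses), "itching")
    assert prev.loc["benefit", "n_reporting"] == 1
    assert prev.loc["benefit", "fraction"] == pytest.approx(0.5)
    assert prev.loc["pd", "n_reporting"] == 0
    nothing = prevalence_by_arm(_mini_cohort(patients, responses), "vomiting")
    assert nothing["n_reporting"].tolist() == [0, 0]


# ------------------------------------------------------------------ survey


def test_survey_summary_splits():
    base = {
        "ease_of_use": "easy",
        "needed_help": "no",
        "questions_understandable": "totally_agree",
        "improved_followup": "yes",
        "benefited": "yes",
        "would_recommend": "yes",
    }
    a = SurveyRecord("A", dict(base))
    b = SurveyRecord("B", {**base, "needed_help": "yes"})
    table = survey_summary([a, b])
    assert table.loc[("needed_help", "yes"), "percent"] == 50
    assert table.loc[("needed_help", "no"), "percent"] == 50
    identical = survey_summary([a, a, a])
    assert identical.loc[("improved_followup", "yes"), "percent"] == 100
    with pytest.raises(ValueError):
        SurveyRecord("C", {**base, "needed_help": "maybe"})


# -------------------------------------------------------------- full matrix


def test_symptom_correlation_matrix_shape_on_fixture(study_cohort):
    matrix = symptom_correlations(study_cohort.responses)
    assert matrix.r.shape == (18, 18)
    assert list(matrix.r.columns) == list(SYMPTOMS)
    defined = matrix.r.to_numpy()[~np.isnan(matrix.r.to_numpy())]
    assert (np.abs(defined) <= 1 + 1e-12).all()
    # symptoms never reported have undefined correlations
    assert matrix.r["blood_in_stool"].isna().all()
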