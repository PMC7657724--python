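"""Grading algorithm vs an independently encoded CTCAE v4.03 oracle.

The oracle below re-states each symptom's patient-reportable CTCAE criteria
as plain Python, written independently of the declarative YAML rule tables,
and every symptom's full (finite) answer domain is swept exhaustively.
"""

import datetime as dt
import itertools

import pytest

from eprowatch.epro_core import (
    GradedResponse,
    GradingError,
    QuestionnaireResponse,
    SYMPTOMS,
    grade_questionnaire,
    grade_symptom,
)

DATE = dt.date(2020, 1, 6)


def _impact3(ans, key="impact"):
    # generic mild / limiting-usual-activities / limiting-self-care ladder
    level = ans[key]
    if level.endswith("self_care") or level == "limits_self_care":
        return 3
    if level == "limits_usual_activities":
        return 2
    return 1


def oracle_grade(symptom_id, ans):
    """CTCAE v4.03 criteria for the 18 tracked symptoms, self-report subset."""
    if ans["present"] is False:
        return 0
    s = symptom_id
    if s in ("blood_in_stool", "hematuria"):
        if ans["needs_urgent_care"]:
            return 3
        return 2 if ans["amount"] in ("clearly_visible", "clearly_bloody_or_clots") else 1
    if s in ("blurred_vision", "dizziness", "headache", "pain_in_joints", "stomach_pain"):
        return _impact3(ans)
    if s == "chest_pain":
        if ans["severity"] == "at_rest_or_limits_self_care":
            return 3
        return 2 if ans["severity"] == "limits_usual_activities" else 1
    if s == "cough":
        if ans["impact"] == "limits_self_care":
            return 3
        return 2 if ans["impact"] == "limits_usual_activities" else 1
    if s == "loss_of_appetite":
        # grade 3: associated with significant weight loss / malnutrition
        if ans["significant_weight_loss"]:
            return 3
        return 2 if ans["eating_less"] else 1
    if s == "diarrhea":
        # 1: increase <4 stools/day; 2: increase 4-6; 3: >=7, hospitalization
        # indicated, or limiting self care
        if (
            ans["hospitalization_level_symptoms"]
            or ans["limits_self_care"]
            or ans["stools_per_day_over_baseline"] >= 7
        ):
            return 3
        return 2 if ans["stools_per_day_over_baseline"] >= 4 else 1
    if s == "fatigue":
        # 2: not relieved by rest (or limiting instrumental ADL); 3: not
        # relieved by rest and limiting self care
        if ans["not_relieved_by_rest"] and ans["limits"] == "limits_self_care":
            return 3
        if ans["not_relieved_by_rest"] or ans["limits"] in (
            "limits_usual_activities",
            "limits_self_care",
        ):
            return 2
        return 1
    if s == "fever":
        # 1: 38.0-39.0 C; 2: >39.0-40.0; 3: >40.0
        return {"t38_to_39": 1, "t39_to_40": 2, "over_40": 3}[ans["max_temperature"]]
    if s == "itching":
        # 2: intense or widespread (or skin changes / intermittent sleep
        # disturbance); 3: widespread and constant, limiting sleep/self care
        if ans["extent"] == "widespread" and ans["constant_or_disturbs_sleep"]:
            return 3
        if ans["extent"] == "widespread" or ans["constant_or_disturbs_sleep"]:
            return 2
        return 1
    if s == "nausea":
        # 2: oral intake decreased; 3: inadequate oral intake
        if ans["barely_eat_or_drink"]:
            return 3
        return 2 if ans["eating_less"] else 1
    if s == "rash":
        # maculo-papular rash by body-surface area: <10% / 10-30% / >30%
        return {"small_area": 1, "up_to_third_of_body": 2, "over_third_of_body": 3}[
            ans["coverage"]
        ]
    if s == "shortness_of_breath":
        # 1: with moderate exertion; 2: with minimal exertion; 3: at rest;
        # 4: life-threatening, urgent intervention indicated
        if ans["needs_urgent_help"]:
            return 4
        return {"strenuous_activity": 1, "everyday_activity": 2, "at_rest": 3}[
            ans["when_breathless"]
        ]
    if s == "vomiting":
        # 1: 1-2 episodes/24h; 2: 3-5; 3: >=6 or urgent intervention
        if ans["needs_urgent_intervention"] or ans["episodes_last_24h"] >= 6:
            return 3
        return 2 if ans["episodes_last_24h"] >= 3 else 1
    raise AssertionError(f"oracle missing symptom {s}")


def _full_domain(symptom):
    """All present=True answer vectors (absent is a single extra point)."""
    items = symptom.followup_items()
    for combo in itertools.product(*(i.domain() for i in items)):
        ans = {"present": True}
        ans.update({i.item_id: v for i, v in zip(items, combo)})
        yield ans


def test_catalog_tracks_all_18_symptoms(catalog):
    assert catalog.ids() == SYMPTOMS
    assert len(set(catalog.ids())) == 18


@pytest.mark.parametrize("symptom_id", SYMPTOMS)
def test_rule_tables_agree_with_ctcae_oracle(catalog, symptom_id):
    """Exhaustive sweep: the declarative rule table equals the hand-coded
    CTCAE criteria at every point of the answer domain."""
    symptom = catalog[symptom_id]
    assert grade_symptom(symptom, {"present": False}) == 0
    n = 0
    for ans in _full_domain(symptom):
        expected = oracle_grade(symptom_id, ans)
        got = grade_symptom(symptom, ans)
        assert got == expected, f"{symptom_id}: {ans} -> {got}, oracle {expected}"
        assert 0 <= got <= symptom.max_grade
        n += 1
    assert n >= 2  # every symptom has a non-trivial domain


@pytest.mark.parametrize("symptom_id", SYMPTOMS)
def test_grades_monotone_under_single_indicator_worsening(catalog, symptom_id):
    """Worsening any one answer item never decreases the grade."""
    symptom = catalog[symptom_id]
    items = symptom.followup_items()
    for ans in _full_domain(symptom):
        base = grade_symptom(symptom, ans)
        for item in items:
            domain = item.domain()
            idx = item.severity_index(ans[item.item_id])
            if idx + 1 >= len(domain):
                continue
            worse = dict(ans)
            worse[item.item_id] = domain[idx + 1]
            assert grade_symptom(symptom, worse) >= base, (
                f"{symptom_id}: worsening {item.item_id} lowered the grade"
            )
    # presence itself is monotone: absent grades 0, present grades >= 1
    assert all(oracle_grade(symptom_id, a) >= 1 for a in _full_domain(symptom))


@pytest.mark.parametrize(
    "symptom_id,answers,expected",
    [
        ("diarrhea", {"present": False}, 0),
        (
            "diarrhea",
            {
                "present": True,
                "stools_per_day_over_baseline": 5,
                "hospitalization_level_symptoms": False,
                "limits_self_care": False,
            },
            2,
        ),
        (
            "vomiting",
            {"present": True, "episodes_last_24h": 1, "needs_urgent_intervention": False},
            1,
        ),
        (
            "vomiting",
            {"present": True, "episodes_last_24h": 7, "needs_urgent_intervention": False},
            3,
        ),
        (
            "shortness_of_breath",
            {"present": True, "when_breathless": "at_rest", "needs_urgent_help": True},
            4,
        ),
    ],
)
def test_reference_gradings(catalog, symptom_id, answers, expected):
    assert grade_symptom(catalog[symptom_id], answers) == expected


def test_incomplete_or_out_of_domain_answers_name_the_item(catalog):
    diarrhea = catalog["diarrhea"]
    with pytest.raises(GradingError, match="present"):
        grade_symptom(diarrhea, {})
    with pytest.raises(GradingError, match="stools_per_day_over_baseline"):
        grade_symptom(diarrhea, {"present": True})
    with pytest.raises(GradingError, match="stools_per_day_over_baseline"):
        grade_symptom(
            diarrhea,
            {
                "present": True,
                "stools_per_day_over_baseline": -1,
                "hospitalization_level_symptoms": False,
                "limits_self_care": False,
            },
        )
    with pytest.raises(GradingError, match="max_temperature"):
        grade_symptom(
            catalog["fever"], {"present": True, "max_temperature": "41C"}
        )


def _all_absent_response(pid="X1", week=1):
    return QuestionnaireResponse(
        patient_id=pid,
        week_index=week,
        answer_date=DATE,
        answers={s: {"present": False} for s in SYMPTOMS},
    )


def test_grade_questionnaire_all_absent_is_all_zero(catalog):
    graded = grade_questionnaire(_all_absent_response(), catalog)
    assert set(graded.grades) == set(SYMPTOMS)
    assert all(g == 0 for g in graded.grades.values())
    assert graded.patient_id == "X1" and graded.week_index == 1
    assert graded.answer_date == DATE


def test_grade_questionnaire_is_local_to_the_symptomatic_answer(catalog):
    resp = _all_absent_response()
    answers = dict(resp.answers)
    answers["fever"] = {"present": True, "max_temperature": "t39_to_40"}
    resp = QuestionnaireResponse(resp.patient_id, resp.week_index, DATE, answers)
    graded = grade_questionnaire(resp, catalog)
    nonzero = {s: g for s, g in graded.grades.items() if g}
    assert nonzero == {"fever": 2}


def test_grade_questionnaire_error_carries_patient_context(catalog):
    answers = {s: {"present": False} for s in SYMPTOMS}
    answers["nausea"] = {"present": True}  # missing follow-up items
    resp = QuestionnaireResponse("P09", 4, DATE, answers)
    with pytest.raises(GradingError, match="P09.*nausea|nausea.*P09"):
        grade_questionnaire(resp, catalog)
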