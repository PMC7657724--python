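"""Urgency algorithm: flag graded questionnaires for care-team attention.

A questionnaire alerts when any symptom reaches the absolute severity
threshold (grade >= 3) or jumps from grade 0 on the previous questionnaire
to grade >= 2.  One decision is issued per questionnaire; it lists every
triggering symptom, and the care team may later annotate the alert's
etiology (cancer, treatment, or unclear).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Iterable

from .epro_core import GradedResponse

ETIOLOGIES = ("cancer", "treatment", "unclear")

REASON_ABSOLUTE = "absolute"
REASON_JUMP = "jump"


@dataclass(frozen=True)
class AlertConfig:
    """Preset alert limits: grade >= `absolute_threshold`, or a rise from
    `jump_from` to >= `jump_to` relative to the previous questionnaire."""

    absolute_threshold: int = 3
    jump_from: int = 0
    jump_to: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.absolute_threshold <= 4:
            raise ValueError("absolute_threshold must be in 1..4")
        if self.jump_to <= self.jump_from:
            raise ValueError("jump_to must exceed jump_from")


DEFAULT_ALERT_CONFIG = AlertConfig()


@dataclass(frozen=True)
class AlertDecision:
    patient_id: str
    week_index: int
    answer_date: dt.date
    triggered: bool
    triggering_symptoms: frozenset[tuple[str, str]] = frozenset()
    etiology: str | None = None

    def __post_init__(self) -> None:
        if self.triggered != bool(self.triggering_symptoms):
            raise ValueError("triggered must hold iff triggering_symptoms is nonempty")
        if self.etiology is not None and not self.triggered:
            raise ValueError("etiology can only be set on a triggered decision")


def evaluate_alert(
    current: GradedResponse,
    reference: GradedResponse | None = None,
    config: AlertConfig = DEFAULT_ALERT_CONFIG,
) -> AlertDecision:
    """Evaluate the alert rule for one graded questionnaire.

    ``reference`` is the patient's most recent prior graded questionnaire;
    when absent (first report) every reference grade is taken as 0, so a
    first report at the jump threshold already alerts — the conservative,
    patient-safe reading of the rule.
    """
    if reference is not None:
        if reference.patient_id != current.patient_id:
            raise ValueError(
                f"reference belongs to patient {reference.patient_id!r}, "
                f"current to {current.patient_id!r}"
            )
        if reference.answer_date > current.answer_date:
            raise ValueError(
                "reference questionnaire is dated after the current one"
            )
    triggers: set[tuple[str, str]] = set()
    for symptom, grade in current.grades.items():
        ref_grade = 0 if reference is None else reference.grades.get(symptom, 0)
        if grade >= config.absolute_threshold:
            triggers.add((symptom, REASON_ABSOLUTE))
        elif ref_grade == config.jump_from and grade >= config.jump_to:
            triggers.add((symptom, REASON_JUMP))
    return AlertDecision(
        patient_id=current.patient_id,
        week_index=current.week_index,
        answer_date=current.answer_date,
        triggered=bool(triggers),
        triggering_symptoms=frozenset(triggers),
    )


def annotate_etiology(decision: AlertDecision, label: str) -> AlertDecision:
    """Attach a physician's etiology label to a triggered decision."""
    if not decision.triggered:
        raise ValueError("cannot annotate etiology on a non-triggered decision")
    if label not in ETIOLOGIES:
        raise ValueError(f"etiology must be one of {ETIOLOGIES}, got {label!r}")
    return dataclasses.replace(decision, etiology=label)


def evaluate_cohort(
    responses: Iterable[GradedResponse],
    config: AlertConfig = DEFAULT_ALERT_CONFIG,
) -> list[AlertDecision]:
    """Evaluate the alert rule over a whole response set.

    Responses are chained per patient in answer-date order (ties broken by
    week index), each evaluated against the patient's previous questionnaire.
    """
    by_patient: dict[str, list[GradedResponse]] = {}
    for r in responses:
        by_patient.setdefault(r.patient_id, []).append(r)
    decisions: list[AlertDecision] = []
    for pid in by_patient:
        chain = sorted(by_patient[pid], key=lambda r: (r.answer_date, r.week_index))
        prev: GradedResponse | None = None
        for r in chain:
            decisions.append(evaluate_alert(r, prev, config))
            prev = r
    return decisions
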