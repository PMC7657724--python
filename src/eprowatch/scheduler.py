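"""Notification scheduling and cohort compliance metrics.

Follow-up runs in 7-day cycles from each patient's treatment-phase entry
until discontinuation or 6 months.  A prompt email opens each cycle; if the
questionnaire is not completed on the prompt day, daily reminders follow for
up to 6 days, stopping at the first answer.  Compliance for week w is the
mean number of answered questionnaires per patient active in week w; week w
covers days [7*(w-1), 7*w) after the patient's start date (1-based, with the
baseline questionnaire at week 0 excluded from the weekly series).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .epro_core import GradedResponse

PROMPT = "prompt"
REMINDER = "reminder"


@dataclass(frozen=True)
class FollowUpPlan:
    patient_id: str
    start_date: dt.date
    end_date: dt.date
    prompt_period: int = 7
    max_reminders: int = 6

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date must not precede start_date")
        if self.max_reminders < 0:
            raise ValueError("max_reminders must be >= 0")

    def n_weeks(self) -> int:
        """Number of follow-up weeks the plan window overlaps."""
        return (self.end_date - self.start_date).days // 7 + 1

    def active_in_week(self, week_index: int) -> bool:
        """Whether the plan window overlaps any day of the given week."""
        if week_index < 1:
            return False
        return (self.end_date - self.start_date).days >= 7 * (week_index - 1)


@dataclass(frozen=True)
class NotificationEvent:
    patient_id: str
    date: dt.date
    event_type: str  # "prompt" | "reminder"


def build_notification_schedule(
    plan: FollowUpPlan, answer_dates: Sequence[dt.date]
) -> list[NotificationEvent]:
    """Generate the prompt/reminder event stream for one patient.

    Within a cycle, a reminder goes out on each day after the prompt until
    the day of the first answer in that cycle (inclusive: an answer later
    that day still receives the morning reminder) or until ``max_reminders``
    is reached; events never extend past the plan window.
    """
    dates = list(answer_dates)
    if dates != sorted(dates):
        raise ValueError("answer_dates must be sorted ascending")
    for d in dates:
        if not plan.start_date <= d <= plan.end_date:
            raise ValueError(f"answer date {d} outside the follow-up window")

    events: list[NotificationEvent] = []
    cycle_start = plan.start_date
    period = dt.timedelta(days=plan.prompt_period)
    while cycle_start <= plan.end_date:
        cycle_end = min(cycle_start + period - dt.timedelta(days=1), plan.end_date)
        events.append(NotificationEvent(plan.patient_id, cycle_start, PROMPT))
        in_cycle = [d for d in dates if cycle_start <= d <= cycle_end]
        first_answer = min(in_cycle) if in_cycle else None
        if first_answer != cycle_start:
            for k in range(1, plan.max_reminders + 1):
                day = cycle_start + dt.timedelta(days=k)
                if day > cycle_end:
                    break
                events.append(NotificationEvent(plan.patient_id, day, REMINDER))
                if first_answer is not None and day >= first_answer:
                    break
        cycle_start += period
    return events


def _active_patients(plans: Iterable[FollowUpPlan], week_index: int) -> set[str]:
    return {p.patient_id for p in plans if p.active_in_week(week_index)}


def compute_compliance(
    responses: Iterable[GradedResponse],
    plans: Iterable[FollowUpPlan],
    week_index: int,
) -> float:
    """Mean questionnaires per active patient in one follow-up week.

    Patients whose plan window does not cover the week are excluded from the
    denominator; the numerator counts every answered questionnaire with that
    week index from an active patient (several per week are possible, so the
    mean may exceed 1).  Raises if no patient is active.
    """
    if week_index < 1:
        raise ValueError("weekly compliance is defined for week_index >= 1")
    active = _active_patients(plans, week_index)
    if not active:
        raise ValueError(f"no patients active in week {week_index}")
    n = sum(
        1
        for r in responses
        if r.week_index == week_index and r.patient_id in active
    )
    return n / len(active)


def compliance_series(
    responses: Iterable[GradedResponse],
    plans: Sequence[FollowUpPlan],
    weeks: Sequence[int] | None = None,
) -> pd.Series:
    """Weekly compliance over all weeks with at least one active patient."""
    responses = list(responses)
    if weeks is None:
        max_week = max((p.n_weeks() for p in plans), default=0)
        weeks = range(1, max_week + 1)
    values = {w: compute_compliance(responses, plans, w) for w in weeks}
    return pd.Series(values, name="mean_questionnaires_per_patient").rename_axis("week")


def compliance_range(series: pd.Series) -> tuple[float, float]:
    """(min, max) of a compliance series over its defined weeks."""
    clean = series.dropna()
    if clean.empty:
        raise ValueError("compliance series is empty")
    return float(clean.min()), float(clean.max())
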