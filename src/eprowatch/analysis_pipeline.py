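"""Cohort-level summaries: grade distributions, alert summaries, Pearson
correlation heat maps with effect-size classes, benefit-stratified symptom
trajectories, and experience-survey tables.

Effect sizes follow the conventional absolute-|r| cutoffs: large >= 0.5,
medium >= 0.3, small >= 0.1 (boundaries inclusive to the stronger class).
Undefined correlations (zero variance or fewer than two complete cases) are
reported as NaN markers, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alert_engine import AlertDecision
from .cohort_simulator import Cohort, SURVEY_QUESTIONS, SurveyRecord
from .epro_core import SYMPTOMS, GradedResponse

GRADE_BUCKETS = ("0", "1", "2", "3-4")

EFFECT_LARGE = "large"
EFFECT_MEDIUM = "medium"
EFFECT_SMALL = "small"
EFFECT_NEGLIGIBLE = "negligible"


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis window and effect-size conventions.

    ``window`` is an inclusive (first, last) follow-up week range; ``None``
    means the full follow-up.  The baseline questionnaire (week 0) is never
    part of a weekly window.
    """

    window: tuple[int, int] | None = None
    effect_cutoffs: tuple[float, float, float] = (0.5, 0.3, 0.1)
    bin_width: int = 2

    def __post_init__(self) -> None:
        large, medium, small = self.effect_cutoffs
        if not (0 < small < medium < large < 1):
            raise ValueError("effect cutoffs must be strictly decreasing within (0, 1)")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")

    def in_window(self, week_index: int) -> bool:
        if self.window is None:
            return True
        return self.window[0] <= week_index <= self.window[1]


FIRST_12_WEEKS = AnalysisConfig(window=(1, 12))
FULL_FOLLOW_UP = AnalysisConfig(window=None)


def grades_frame(responses: Iterable[GradedResponse]) -> pd.DataFrame:
    """Long-to-wide table: one row per questionnaire, one column per symptom."""
    records = [
        {
            "patient_id": r.patient_id,
            "week_index": r.week_index,
            "answer_date": r.answer_date,
            **{s: r.grades.get(s, 0) for s in SYMPTOMS},
        }
        for r in responses
    ]
    return pd.DataFrame(
        records, columns=["patient_id", "week_index", "answer_date", *SYMPTOMS]
    )


def _windowed(responses: Iterable[GradedResponse], config: AnalysisConfig):
    return [r for r in responses if config.in_window(r.week_index)]


def grade_distribution(
    responses: Iterable[GradedResponse],
    config: AnalysisConfig = FULL_FOLLOW_UP,
) -> pd.DataFrame:
    """Per-symptom percentage of questionnaires in each grade bucket.

    Buckets are {0, 1, 2, 3-4}; the denominator is the number of answered
    questionnaires in the window, so each row sums to 100 up to rounding.
    """
    rows = _windowed(responses, config)
    if not rows:
        raise ValueError("no questionnaires in the analysis window")
    n = len(rows)
    out = {}
    for sym in SYMPTOMS:
        counts = [0, 0, 0, 0]
        for r in rows:
            g = r.grades.get(sym, 0)
            counts[min(g, 3)] += 1
        out[sym] = [100.0 * c / n for c in counts]
    frame = pd.DataFrame.from_dict(out, orient="index", columns=GRADE_BUCKETS)
    frame.index.name = "symptom"
    return frame


@dataclass(frozen=True)
class AlertSummary:
    n_questionnaires: int
    n_alerts: int
    etiology_counts: Mapping[str, int]
    by_symptom: Mapping[str, int]

    @property
    def rate(self) -> float:
        return self.n_alerts / self.n_questionnaires


def alert_summary(
    decisions: Iterable[AlertDecision],
    responses: Iterable[GradedResponse],
    config: AnalysisConfig = FIRST_12_WEEKS,
) -> AlertSummary:
    """Alert rate, etiology counts and by-symptom trigger counts in-window.

    The by-symptom counts may sum to more than the number of alerts since
    one questionnaire can trigger on several symptoms.
    """
    responses = _windowed(responses, config)
    keys = {(r.patient_id, r.answer_date) for r in responses}
    decisions = [d for d in decisions if config.in_window(d.week_index)]
    for d in decisions:
        if (d.patient_id, d.answer_date) not in keys:
            raise ValueError(
                f"alert decision for {d.patient_id} on {d.answer_date} has no "
                f"matching questionnaire in the window"
            )
    if not responses:
        raise ValueError("no questionnaires in the analysis window")
    triggered = [d for d in decisions if d.triggered]
    etiology: dict[str, int] = {}
    by_symptom: dict[str, int] = {}
    for d in triggered:
        if d.etiology is not None:
            etiology[d.etiology] = etiology.get(d.etiology, 0) + 1
        for sym, _reason in d.triggering_symptoms:
            by_symptom[sym] = by_symptom.get(sym, 0) + 1
    by_symptom = dict(sorted(by_symptom.items(), key=lambda kv: (-kv[1], kv[0])))
    return AlertSummary(
        n_questionnaires=len(responses),
        n_alerts=len(triggered),
        etiology_counts=etiology,
        by_symptom=by_symptom,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix with per-cell complete-case counts."""

    r: pd.DataFrame
    n: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)

    def __post_init__(self) -> None:
        vals = self.r.to_numpy(dtype=float)
        if np.nanmax(np.abs(vals), initial=0.0) > 1 + 1e-9:
            raise ValueError("|r| must not exceed 1")


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson product-moment correlations of a numeric table.

    Pairs with fewer than two complete cases or a zero-variance column get
    an NaN marker.  The diagonal is 1 for columns with variance.
    """
    numeric = table.apply(pd.to_numeric)
    if len(numeric) < 2:
        raise ValueError("need at least two observations")
    r = numeric.corr(method="pearson", min_periods=2)
    notnull = numeric.notna().astype(int)
    n = pd.DataFrame(
        notnull.T.to_numpy() @ notnull.to_numpy(),
        index=numeric.columns,
        columns=numeric.columns,
    )
    return CorrelationMatrix(r=r, n=n)


def symptom_correlations(
    responses: Iterable[GradedResponse],
    config: AnalysisConfig = FULL_FOLLOW_UP,
) -> CorrelationMatrix:
    """Symptom-by-symptom correlation with one observation per questionnaire."""
    frame = grades_frame(_windowed(responses, config))
    return pearson_matrix(frame[list(SYMPTOMS)])


def effect_size_class(r: float, config: AnalysisConfig = FULL_FOLLOW_UP) -> str:
    """Classify |r| as large / medium / small / negligible."""
    if r is None or (isinstance(r, float) and math.isnan(r)):
        raise ValueError("effect size is undefined for an undefined correlation")
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    large, medium, small = config.effect_cutoffs
    a = abs(r)
    if a >= large:
        return EFFECT_LARGE
    if a >= medium:
        return EFFECT_MEDIUM
    if a >= small:
        return EFFECT_SMALL
    return EFFECT_NEGLIGIBLE


def patient_symptom_summary(
    cohort: Cohort, config: AnalysisConfig = FULL_FOLLOW_UP
) -> pd.DataFrame:
    """One row per evaluable patient: benefit indicator plus the patient's
    mean grade per symptom over the window (the patient-level observation
    unit used for benefit correlations)."""
    frame = grades_frame(cohort.responses)
    if config.window is not None:
        lo, hi = config.window
        frame = frame[(frame.week_index >= lo) & (frame.week_index <= hi)]
    rows = []
    for p in cohort.evaluable_patients():
        sub = frame[frame.patient_id == p.patient_id]
        if sub.empty:
            continue
        row = {"patient_id": p.patient_id, "benefit": int(p.clinical_benefit)}
        for s in SYMPTOMS:
            row[s] = float(sub[s].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "benefit", *SYMPTOMS])


def benefit_correlation(
    cohort: Cohort, config: AnalysisConfig = FULL_FOLLOW_UP
) -> pd.DataFrame:
    """Per-symptom Pearson r between clinical benefit (1 = CR/PR/SD, 0 = PD)
    and the patient's mean symptom grade over the window.

    Returns a frame indexed by symptom with columns r, n and effect_class
    (None where r is undefined)."""
    table = patient_symptom_summary(cohort, config)
    if table.empty or table.benefit.nunique() < 2:
        raise ValueError("need evaluable patients in both benefit classes")
    benefit = table["benefit"].to_numpy(dtype=float)
    out = []
    for s in SYMPTOMS:
        x = table[s].to_numpy(dtype=float)
        if len(x) < 2 or np.std(x) == 0 or np.std(benefit) == 0:
            r = float("nan")
            klass = None
        else:
            r = float(np.corrcoef(benefit, x)[0, 1])
            klass = effect_size_class(r, config)
        out.append({"symptom": s, "r": r, "n": len(x), "effect_class": klass})
    return pd.DataFrame(out).set_index("symptom")


def binned_average_grade(
    cohort: Cohort,
    symptom: str,
    group: str = "all",
    config: AnalysisConfig = FIRST_12_WEEKS,
) -> pd.Series:
    """Mean symptom grade per consecutive week bin (default 2-week bins).

    ``group`` selects all evaluable patients, the clinical-benefit arm, or
    the PD arm.  Empty bins are NaN.
    """
    if symptom not in SYMPTOMS:
        raise ValueError(f"unknown symptom {symptom!r}")
    if group not in ("all", "benefit", "pd"):
        raise ValueError("group must be one of 'all', 'benefit', 'pd'")
    members = set()
    for p in cohort.evaluable_patients():
        if (
            group == "all"
            or (group == "benefit" and p.clinical_benefit)
            or (group == "pd" and not p.clinical_benefit)
        ):
            members.add(p.patient_id)
    frame = grades_frame(cohort.responses)
    lo, hi = config.window if config.window else (1, int(frame.week_index.max()))
    frame = frame[
        frame.patient_id.isin(members)
        & (frame.week_index >= lo)
        & (frame.week_index <= hi)
    ]
    values = {}
    for start in range(lo, hi + 1, config.bin_width):
        end = min(start + config.bin_width - 1, hi)
        sub = frame[(frame.week_index >= start) & (frame.week_index <= end)]
        label = f"{start}-{end}" if end > start else str(start)
        values[label] = float(sub[symptom].mean()) if len(sub) else float("nan")
    return pd.Series(values, name=f"mean_{symptom}_grade").rename_axis("weeks")


def prevalence_by_arm(
    cohort: Cohort,
    symptom: str,
    config: AnalysisConfig = FULL_FOLLOW_UP,
) -> pd.DataFrame:
    """Fraction of evaluable patients per arm reporting the symptom (grade
    >= 1 on any questionnaire in the window)."""
    if symptom not in SYMPTOMS:
        raise ValueError(f"unknown symptom {symptom!r}")
    reporters = {
        r.patient_id
        for r in _windowed(cohort.responses, config)
        if r.grades.get(symptom, 0) >= 1
    }
    rows = []
    for arm, want_benefit in (("benefit", True), ("pd", False)):
        members = [
            p for p in cohort.evaluable_patients() if p.clinical_benefit == want_benefit
        ]
        if not members:
            rows.append({"arm": arm, "n_reporting": 0, "n_patients": 0,
                         "fraction": float("nan")})
            continue
        k = sum(1 for p in members if p.patient_id in reporters)
        rows.append(
            {
                "arm": arm,
                "n_reporting": k,
                "n_patients": len(members),
                "fraction": k / len(members),
            }
        )
    return pd.DataFrame(rows).set_index("arm")


def survey_summary(surveys: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Per-question answer counts and whole percentages (rows per option)."""
    if not surveys:
        raise ValueError("no survey records")
    n = len(surveys)
    rows = []
    for q, options in SURVEY_QUESTIONS.items():
        for opt in options:
            k = sum(1 for s in surveys if s.answers[q] == opt)
            rows.append(
                {
                    "question": q,
                    "option": opt,
                    "count": k,
                    "percent": round(100.0 * k / n),
                }
            )
    return pd.DataFrame(rows).set_index(["question", "option"])


def plot_correlation_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Export a correlation heat map (red = negative, blue = positive)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(10, 8))
    sns.heatmap(
        matrix.r,
        vmin=-1.0,
        vmax=1.0,
        cmap="RdBu",
        square=True,
        linewidths=0.5,
        ax=ax,
        cbar_kws={"label": "Pearson r"},
    )
    ax.set_xlabel("")
    ax.set_ylabel("")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
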