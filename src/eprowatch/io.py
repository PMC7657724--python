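"""CSV/JSON serialization of cohorts, alerts and analysis bundles.

File conventions: UTF-8 CSV with a header row, ISO-8601 dates, 1-based week
indices (0 = baseline questionnaire).  Graded responses carry one
``<symptom>.grade`` column per catalog symptom; raw questionnaires carry
``<symptom>.<item>`` columns.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from . import analysis_pipeline as ap
from .alert_engine import (
    AlertConfig,
    AlertDecision,
    DEFAULT_ALERT_CONFIG,
    annotate_etiology,
    evaluate_cohort,
)
from .cohort_simulator import (
    Cohort,
    Patient,
    SimulationParams,
    SURVEY_QUESTIONS,
    SurveyRecord,
    build_study_fixture,
    simulate_cohort,
    study_fixture_decisions,
)
from .epro_core import (
    GradedResponse,
    QuestionnaireResponse,
    SYMPTOMS,
    SymptomCatalog,
    load_catalog,
)
from .scheduler import FollowUpPlan, build_notification_schedule, compliance_series


class CohortLoadError(ValueError):
    """Raised when cohort CSV files violate the schema."""


PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "tumor_type", "stage", "ecog",
    "autoimmune_disease", "best_response",
]


def _date(value: Any, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as err:
        raise CohortLoadError(f"{where}: invalid date {value!r}") from err


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    patients = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "sex": p.sex,
                "tumor_type": p.tumor_type,
                "stage": p.stage,
                "ecog": p.ecog,
                "autoimmune_disease": p.autoimmune_disease,
                "best_response": p.best_response or "",
            }
            for p in cohort.patients
        ],
        columns=PATIENT_COLUMNS,
    )
    paths["patients"] = out / "patients.csv"
    patients.to_csv(paths["patients"], index=False)

    responses = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "week_index": r.week_index,
                "answer_date": r.answer_date.isoformat(),
                **{f"{s}.grade": r.grades.get(s, 0) for s in SYMPTOMS},
            }
            for r in cohort.responses
        ],
        columns=["patient_id", "week_index", "answer_date"]
        + [f"{s}.grade" for s in SYMPTOMS],
    )
    paths["responses"] = out / "responses.csv"
    responses.to_csv(paths["responses"], index=False)

    plans = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "start_date": p.start_date.isoformat(),
                "end_date": p.end_date.isoformat(),
            }
            for p in cohort.plans
        ],
        columns=["patient_id", "start_date", "end_date"],
    )
    paths["plans"] = out / "plans.csv"
    plans.to_csv(paths["plans"], index=False)

    surveys = pd.DataFrame(
        [
            {"patient_id": s.patient_id, **{q: s.answers[q] for q in SURVEY_QUESTIONS}}
            for s in cohort.surveys
        ],
        columns=["patient_id", *SURVEY_QUESTIONS],
    )
    paths["surveys"] = out / "surveys.csv"
    surveys.to_csv(paths["surveys"], index=False)
    return paths


def write_alerts(decisions: Sequence[AlertDecision], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "week_index": d.week_index,
                "answer_date": d.answer_date.isoformat(),
                "triggered": d.triggered,
                "triggering_symptoms": ";".join(
                    f"{s}:{reason}" for s, reason in sorted(d.triggering_symptoms)
                ),
                "etiology": d.etiology or "",
            }
            for d in decisions
        ],
        columns=[
            "patient_id", "week_index", "answer_date", "triggered",
            "triggering_symptoms", "etiology",
        ],
    )
    frame.to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def read_responses(path: str | Path) -> list[GradedResponse]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    grade_cols = {f"{s}.grade": s for s in SYMPTOMS}
    unknown = [
        c
        for c in frame.columns
        if c.endswith(".grade") and c not in grade_cols
    ]
    if unknown:
        raise CohortLoadError(f"{path}: unknown symptom columns {unknown}")
    missing = [c for c in grade_cols if c not in frame.columns]
    if missing:
        raise CohortLoadError(f"{path}: missing grade columns {missing}")
    responses = []
    for i, row in frame.iterrows():
        where = f"{path}, row {i + 2}"  # 1-based + header
        grades = {}
        for col, sym in grade_cols.items():
            g = row[col]
            if pd.isna(g) or int(g) not in (0, 1, 2, 3, 4):
                raise CohortLoadError(f"{where}: invalid grade {g!r} for {sym}")
            grades[sym] = int(g)
        responses.append(
            GradedResponse(
                patient_id=str(row["patient_id"]),
                week_index=int(row["week_index"]),
                answer_date=_date(row["answer_date"], where),
                grades=grades,
            )
        )
    return responses


def read_plans(path: str | Path) -> list[FollowUpPlan]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    plans = []
    for i, row in frame.iterrows():
        where = f"{path}, row {i + 2}"
        plans.append(
            FollowUpPlan(
                patient_id=str(row["patient_id"]),
                start_date=_date(row["start_date"], where),
                end_date=_date(row["end_date"], where),
            )
        )
    return plans


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load and validate a cohort from its CSV directory.

    Referential integrity is enforced: every response, plan and survey row
    must reference a registered patient.
    """
    in_dir = Path(in_dir)
    ppath = in_dir / "patients.csv"
    patients_frame = pd.read_csv(ppath, dtype={"patient_id": str})
    patients = []
    for i, row in patients_frame.iterrows():
        where = f"{ppath}, row {i + 2}"
        best = row.get("best_response")
        best = None if pd.isna(best) or best == "" else str(best)
        if best is not None and best not in ("CR", "PR", "SD", "PD"):
            raise CohortLoadError(f"{where}: invalid best_response {best!r}")
        patients.append(
            Patient(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                tumor_type=str(row["tumor_type"]),
                stage=str(row["stage"]),
                ecog=int(row["ecog"]),
                autoimmune_disease=bool(row["autoimmune_disease"]),
                best_response=best,
            )
        )
    ids = {p.patient_id for p in patients}

    responses = read_responses(in_dir / "responses.csv")
    for i, r in enumerate(responses):
        if r.patient_id not in ids:
            raise CohortLoadError(
                f"{in_dir / 'responses.csv'}, row {i + 2}: unknown patient "
                f"{r.patient_id!r}"
            )
    plans = read_plans(in_dir / "plans.csv")
    for i, p in enumerate(plans):
        if p.patient_id not in ids:
            raise CohortLoadError(
                f"{in_dir / 'plans.csv'}, row {i + 2}: unknown patient "
                f"{p.patient_id!r}"
            )

    surveys = []
    spath = in_dir / "surveys.csv"
    if spath.exists():
        sframe = pd.read_csv(spath, dtype=str)
        for i, row in sframe.iterrows():
            where = f"{spath}, row {i + 2}"
            if row["patient_id"] not in ids:
                raise CohortLoadError(f"{where}: unknown patient {row['patient_id']!r}")
            try:
                surveys.append(
                    SurveyRecord(
                        patient_id=row["patient_id"],
                        answers={q: row[q] for q in SURVEY_QUESTIONS},
                    )
                )
            except (KeyError, ValueError) as err:
                raise CohortLoadError(f"{where}: {err}") from err
    return Cohort(patients=patients, responses=responses, plans=plans, surveys=surveys)


def read_alerts(path: str | Path) -> list[AlertDecision]:
    frame = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    decisions = []
    for i, row in frame.iterrows():
        where = f"{path}, row {i + 2}"
        raw = str(row["triggering_symptoms"])
        triggers = frozenset(
            tuple(part.split(":", 1)) for part in raw.split(";") if part
        )
        d = AlertDecision(
            patient_id=str(row["patient_id"]),
            week_index=int(row["week_index"]),
            answer_date=_date(row["answer_date"], where),
            triggered=str(row["triggered"]).lower() == "true",
            triggering_symptoms=triggers,
        )
        if row.get("etiology"):
            d = annotate_etiology(d, str(row["etiology"]))
        decisions.append(d)
    return decisions


def read_raw_responses(
    path: str | Path, catalog: SymptomCatalog | None = None
) -> list[QuestionnaireResponse]:
    """Read raw questionnaires (``<symptom>.<item>`` columns).

    Empty cells on follow-up items are treated as "not asked" (symptom not
    present); the grading layer enforces completeness when present.
    """
    catalog = catalog or load_catalog()
    frame = pd.read_csv(path, dtype={"patient_id": str})
    responses = []
    for i, row in frame.iterrows():
        where = f"{path}, row {i + 2}"
        answers: dict[str, dict[str, Any]] = {}
        for symptom in catalog:
            vec: dict[str, Any] = {}
            for item in symptom.items:
                col = f"{symptom.symptom_id}.{item.item_id}"
                if col not in frame.columns:
                    continue
                val = row[col]
                if pd.isna(val) or val == "":
                    continue
                if item.kind == "boolean":
                    vec[item.item_id] = str(val).strip().lower() in ("true", "yes", "1")
                elif item.kind == "count":
                    vec[item.item_id] = int(val)
                else:
                    vec[item.item_id] = str(val)
            # a symptom block left entirely blank means "not present"
            vec.setdefault("present", False)
            answers[symptom.symptom_id] = vec
        responses.append(
            QuestionnaireResponse(
                patient_id=str(row["patient_id"]),
                week_index=int(row["week_index"]),
                answer_date=_date(row["answer_date"], where),
                answers=answers,
            )
        )
    return responses


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """One reproducible analysis run.

    Exactly one of ``input_dir`` (cohort CSVs), ``params_path`` (simulation
    parameter YAML) or ``fixture`` (the deterministic study cohort) selects
    the input.
    """

    out_dir: str | Path
    input_dir: str | Path | None = None
    params_path: str | Path | None = None
    fixture: bool = False
    window: tuple[int, int] | None = (1, 12)
    alert_config: AlertConfig = DEFAULT_ALERT_CONFIG
    seed: int | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        sources = sum(
            [self.input_dir is not None, self.params_path is not None, self.fixture]
        )
        if sources != 1:
            raise ValueError(
                "exactly one of input_dir, params_path or fixture must be given"
            )


def _load_source(config: RunConfig) -> tuple[Cohort, list[AlertDecision]]:
    if config.fixture:
        cohort = build_study_fixture()
        return cohort, study_fixture_decisions(cohort)
    if config.params_path is not None:
        params = SimulationParams.from_yaml(config.params_path)
        if config.seed is not None:
            params = dataclasses.replace(params, seed=config.seed)
        cohort = simulate_cohort(params)
        return cohort, evaluate_cohort(cohort.responses, config.alert_config)
    cohort = read_cohort(config.input_dir)
    alerts_path = Path(config.input_dir) / "alerts.csv"
    if alerts_path.exists():
        return cohort, read_alerts(alerts_path)
    return cohort, evaluate_cohort(cohort.responses, config.alert_config)


def run_pipeline(config: RunConfig) -> dict:
    """Execute grade -> alert -> compliance -> analysis and write the bundle.

    Returns the JSON report as a dict; identical inputs and seed give
    byte-identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        cohort, decisions = _load_source(config)
        if not cohort.responses:
            raise ValueError("cohort contains no questionnaires")

        stage = "alerts"
        write_alerts(decisions, out / "alerts.csv")
        window_cfg = ap.AnalysisConfig(window=config.window)
        summary = ap.alert_summary(decisions, cohort.responses, window_cfg)

        stage = "compliance"
        series = compliance_series(cohort.responses, cohort.plans)
        series.round(6).to_csv(out / "compliance.csv", header=True)

        stage = "analysis"
        dist = ap.grade_distribution(cohort.responses)
        dist.round(3).to_csv(out / "grade_distribution.csv")
        corr = ap.symptom_correlations(cohort.responses, window_cfg)
        corr.r.round(6).to_csv(out / "symptom_correlations.csv")
        try:
            bcorr = ap.benefit_correlation(cohort, window_cfg)
            bcorr.round({"r": 6}).to_csv(out / "benefit_correlation.csv")
        except ValueError:
            bcorr = None
        if cohort.surveys:
            ap.survey_summary(cohort.surveys).to_csv(out / "survey_summary.csv")
        if config.make_plots:
            ap.plot_correlation_heatmap(corr, out / "symptom_correlations.png")

        report = {
            "n_patients": len(cohort.patients),
            "n_questionnaires": len(cohort.responses),
            "window": list(config.window) if config.window else None,
            "alerts": {
                "n_questionnaires_in_window": summary.n_questionnaires,
                "n_alerts": summary.n_alerts,
                "rate_percent": round(100.0 * summary.rate, 1),
                "etiology": dict(summary.etiology_counts),
                "by_symptom": dict(summary.by_symptom),
            },
            "compliance": {
                "min": round(float(series.min()), 3),
                "max": round(float(series.max()), 3),
            },
        }
        if bcorr is not None:
            report["benefit_correlation"] = {
                s: (None if pd.isna(row.r) else round(float(row.r), 4))
                for s, row in bcorr.iterrows()
            }
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err


def write_schedule(
    cohort: Cohort, path: str | Path
) -> Path:
    """Derive and write the prompt/reminder event stream for every patient."""
    dates_by_patient: dict[str, list[dt.date]] = {}
    for r in cohort.responses:
        dates_by_patient.setdefault(r.patient_id, []).append(r.answer_date)
    rows = []
    for plan in cohort.plans:
        answers = sorted(dates_by_patient.get(plan.patient_id, []))
        for ev in build_notification_schedule(plan, answers):
            rows.append(
                {
                    "patient_id": ev.patient_id,
                    "date": ev.date.isoformat(),
                    "type": ev.event_type,
                }
            )
    frame = pd.DataFrame(rows, columns=["patient_id", "date", "type"])
    frame.to_csv(path, index=False)
    return Path(path)
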