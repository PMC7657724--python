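"""Symptom catalog, questionnaire data model and CTCAE severity grading.

The questionnaire tracks 18 symptoms typical of immune-related adverse
events under anti-PD-(L)1 therapy.  Each symptom is defined declaratively
(question items plus an ordered rule table) in a YAML catalog derived from
NCI-CTCAE v4.03 term criteria restricted to what a patient can self-report,
and the grading algorithm maps a patient's answers to a grade
g in {0 (none), 1 (mild), 2 (moderate), 3 (severe), 4 (life-threatening)}.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

#: The 18 tracked symptoms, in canonical (alphabetical-by-question) order.
SYMPTOMS: tuple[str, ...] = (
    "blood_in_stool",
    "hematuria",
    "blurred_vision",
    "chest_pain",
    "cough",
    "loss_of_appetite",
    "diarrhea",
    "dizziness",
    "fatigue",
    "fever",
    "headache",
    "itching",
    "nausea",
    "pain_in_joints",
    "rash",
    "shortness_of_breath",
    "stomach_pain",
    "vomiting",
)

GRADES = (0, 1, 2, 3, 4)


class GradingError(ValueError):
    """Raised for incomplete or out-of-domain questionnaire answers."""


class CatalogError(ValueError):
    """Raised for a malformed symptom catalog."""


@dataclass(frozen=True)
class AnswerItem:
    """A single question item with its answer domain.

    Severity is ordered within the domain: for booleans ``True`` is worse,
    for counts larger is worse, and for categories later levels are worse.
    """

    item_id: str
    prompt: str
    kind: str  # "boolean" | "category" | "count"
    levels: tuple[str, ...] = ()
    max_count: int | None = None

    def domain(self) -> tuple[Any, ...]:
        """Enumerate the full (finite) answer domain, least severe first."""
        if self.kind == "boolean":
            return (False, True)
        if self.kind == "category":
            return self.levels
        return tuple(range(0, (self.max_count or 0) + 1))

    def validate(self, value: Any) -> None:
        if self.kind == "boolean":
            if not isinstance(value, bool):
                raise GradingError(
                    f"item {self.item_id!r}: expected a yes/no answer, got {value!r}"
                )
        elif self.kind == "category":
            if value not in self.levels:
                raise GradingError(
                    f"item {self.item_id!r}: {value!r} is not one of {self.levels}"
                )
        else:  # count
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise GradingError(
                    f"item {self.item_id!r}: expected a non-negative count, got {value!r}"
                )
            if self.max_count is not None and value > self.max_count:
                raise GradingError(
                    f"item {self.item_id!r}: count {value} exceeds the reportable "
                    f"maximum {self.max_count}"
                )

    def severity_index(self, value: Any) -> int:
        """Position of ``value`` in the worsening order of the domain."""
        if self.kind == "boolean":
            return int(value)
        if self.kind == "category":
            return self.levels.index(value)
        return int(value)


@dataclass(frozen=True)
class GradeRule:
    """One first-match rule: a conjunction of item conditions -> grade."""

    grade: int
    conditions: tuple[tuple[str, str, Any], ...] = ()  # (item_id, op, operand)

    def matches(self, answers: Mapping[str, Any], items: Mapping[str, AnswerItem]) -> bool:
        for item_id, op, operand in self.conditions:
            item = items[item_id]
            val = item.severity_index(answers[item_id])
            ref = item.severity_index(operand)
            if op == "eq" and val != ref:
                return False
            if op == "ge" and val < ref:
                return False
            if op == "le" and val > ref:
                return False
        return True


@dataclass(frozen=True)
class SymptomDef:
    """Declarative definition of one symptom block."""

    symptom_id: str
    name: str
    items: tuple[AnswerItem, ...]
    rules: tuple[GradeRule, ...]
    max_grade: int = 4

    def __post_init__(self) -> None:
        if not any(i.item_id == "present" for i in self.items):
            raise CatalogError(f"{self.symptom_id}: missing 'present' item")
        if self.max_grade not in (1, 2, 3, 4):
            raise CatalogError(f"{self.symptom_id}: max_grade must be 1..4")
        for rule in self.rules:
            if not 0 <= rule.grade <= self.max_grade:
                raise CatalogError(
                    f"{self.symptom_id}: rule grade {rule.grade} exceeds "
                    f"max_grade {self.max_grade}"
                )
        if self.rules and self.rules[-1].conditions:
            raise CatalogError(f"{self.symptom_id}: last rule must be a catch-all")

    @property
    def item_map(self) -> dict[str, AnswerItem]:
        return {i.item_id: i for i in self.items}

    def followup_items(self) -> tuple[AnswerItem, ...]:
        return tuple(i for i in self.items if i.item_id != "present")


@dataclass(frozen=True)
class SymptomCatalog:
    """The full 18-symptom questionnaire definition."""

    symptoms: tuple[SymptomDef, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = tuple(s.symptom_id for s in self.symptoms)
        if sorted(ids) != sorted(SYMPTOMS):
            missing = set(SYMPTOMS) - set(ids)
            extra = set(ids) - set(SYMPTOMS)
            raise CatalogError(
                f"catalog must define exactly the 18 tracked symptoms "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )

    def __iter__(self) -> Iterator[SymptomDef]:
        return iter(self.symptoms)

    def __getitem__(self, symptom_id: str) -> SymptomDef:
        for s in self.symptoms:
            if s.symptom_id == symptom_id:
                return s
        raise KeyError(symptom_id)

    def ids(self) -> tuple[str, ...]:
        return tuple(s.symptom_id for s in self.symptoms)


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One patient-week of raw answers (week 0 is the baseline)."""

    patient_id: str
    week_index: int
    answer_date: dt.date
    answers: Mapping[str, Mapping[str, Any]]

    def __post_init__(self) -> None:
        if self.week_index < 0:
            raise ValueError("week_index must be >= 0")


@dataclass(frozen=True)
class GradedResponse:
    """One patient-week of per-symptom CTCAE grades."""

    patient_id: str
    week_index: int
    answer_date: dt.date
    grades: Mapping[str, int]

    def __post_init__(self) -> None:
        for sym, g in self.grades.items():
            if g not in GRADES:
                raise ValueError(f"{sym}: grade {g!r} outside 0..4")


def _parse_item(raw: Mapping[str, Any]) -> AnswerItem:
    dom = raw.get("domain") or {}
    kind = dom.get("type")
    if kind not in ("boolean", "category", "count"):
        raise CatalogError(f"item {raw.get('id')!r}: unknown domain type {kind!r}")
    return AnswerItem(
        item_id=raw["id"],
        prompt=raw.get("prompt", ""),
        kind=kind,
        levels=tuple(dom.get("levels", ())),
        max_count=dom.get("max"),
    )


def _parse_rule(raw: Mapping[str, Any]) -> GradeRule:
    conds: list[tuple[str, str, Any]] = []
    for item_id, spec in (raw.get("when") or {}).items():
        for op, operand in spec.items():
            if op not in ("eq", "ge", "le"):
                raise CatalogError(f"unknown rule operator {op!r}")
            conds.append((item_id, op, operand))
    return GradeRule(grade=int(raw["grade"]), conditions=tuple(conds))


def load_catalog(path: str | Path | None = None) -> SymptomCatalog:
    """Load the symptom catalog from YAML (packaged default if no path)."""
    if path is None:
        ref = resources.files("eprowatch").joinpath("data/symptom_catalog.yaml")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    symptoms = []
    for block in doc["symptoms"]:
        items = tuple(_parse_item(i) for i in block["items"])
        rules = tuple(_parse_rule(r) for r in block["rules"])
        symptoms.append(
            SymptomDef(
                symptom_id=block["id"],
                name=block.get("name", block["id"]),
                items=items,
                rules=rules,
                max_grade=int(block.get("max_grade", 4)),
            )
        )
    return SymptomCatalog(symptoms=tuple(symptoms), version=str(doc.get("version", "?")))


def grade_symptom(symptom: SymptomDef, answers: Mapping[str, Any]) -> int:
    """Grade one symptom from its answer vector.

    "Not present" always grades 0; follow-up items are then not required.
    When the symptom is present the full answer vector must be supplied and
    the first matching rule in the symptom's ordered rule table fires.
    """
    if "present" not in answers:
        raise GradingError(f"{symptom.symptom_id}: missing item 'present'")
    items = symptom.item_map
    items["present"].validate(answers["present"])
    if answers["present"] is False:
        return 0
    for item in symptom.followup_items():
        if item.item_id not in answers:
            raise GradingError(
                f"{symptom.symptom_id}: missing answer for item {item.item_id!r}"
            )
        item.validate(answers[item.item_id])
    unknown = set(answers) - set(items)
    if unknown:
        raise GradingError(
            f"{symptom.symptom_id}: unknown items {sorted(unknown)}"
        )
    for rule in symptom.rules:
        if rule.matches(answers, items):
            return rule.grade
    raise GradingError(f"{symptom.symptom_id}: no grading rule matched")  # pragma: no cover


def grade_questionnaire(
    response: QuestionnaireResponse, catalog: SymptomCatalog
) -> GradedResponse:
    """Apply the severity algorithm to every symptom of a questionnaire."""
    grades: dict[str, int] = {}
    for symptom in catalog:
        sid = symptom.symptom_id
        if sid not in response.answers:
            raise GradingError(
                f"questionnaire of patient {response.patient_id!r}, week "
                f"{response.week_index}: no answers for symptom {sid!r}"
            )
        try:
            grades[sid] = grade_symptom(symptom, response.answers[sid])
        except GradingError as err:
            raise GradingError(
                f"patient {response.patient_id!r}, week {response.week_index}: {err}"
            ) from err
    return GradedResponse(
        patient_id=response.patient_id,
        week_index=response.week_index,
        answer_date=response.answer_date,
        grades=grades,
    )
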