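"""Survey schema and scoring rubric as declarative, validated data.

The instrument is a multiple-choice survey whose scored questions map answer
options to point values on a 1-5 scale. Five scored questions belong to each
of the four maturity domains (Access, Consultation, Technology, Evidence),
giving each domain an attainable maximum of 25 points. The engine is
rubric-agnostic: everything it needs — question texts, answer options, point
values, multi-select aggregation rules — lives in one human-editable YAML
file, of which the shipped ``acte_mtb_v1`` instrument is one instance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigError, RubricValidationError

DOMAINS = ("Access", "Consultation", "Technology", "Evidence")

#: Attainable per-question maximum and per-domain budget.
QUESTION_MAX = 5.0
DOMAIN_MAX = 25.0
QUESTIONS_PER_DOMAIN = 5

#: Shipped full-survey shape: 59 questions, 56 required multiple-choice,
#: 3 optional free-text.
FULL_SURVEY_TOTAL = 59
FULL_SURVEY_REQUIRED = 56
FULL_SURVEY_FREETEXT = 3

AggregationRule = Literal["max", "sum_capped", "count_banded"]
ResponseMode = Literal["single-choice", "multi-select", "free-text"]


class AnswerOption(BaseModel):
    """One selectable answer; ``points`` present only on scored questions."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    code: str
    label: str
    points: Optional[float] = None
    numeric_value: Optional[float] = None


class Question(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    text: str
    category: str
    response_mode: ResponseMode
    scored: bool = False
    domain: Optional[str] = None
    aggregation: AggregationRule = "max"
    short_label: Optional[str] = None
    options: tuple[AnswerOption, ...] = ()

    @model_validator(mode="after")
    def _basic_shape(self) -> "Question":
        if self.response_mode == "free-text" and self.options:
            raise ValueError(f"free-text question {self.id!r} must not carry options")
        return self

    def option(self, code: str) -> AnswerOption:
        for opt in self.options:
            if opt.code == code:
                return opt
        raise KeyError(code)

    @property
    def option_codes(self) -> tuple[str, ...]:
        return tuple(o.code for o in self.options)

    def attainable_points(self) -> tuple[float, ...]:
        """Sorted grid of point values reachable under the aggregation rule."""
        if not self.scored:
            return ()
        if self.response_mode == "single-choice" or self.aggregation == "max":
            grid = {o.points for o in self.options if o.points is not None}
        elif self.aggregation == "count_banded":
            grid = {min(QUESTION_MAX, k) for k in range(1, len(self.options) + 1)}
        elif self.aggregation == "sum_capped":
            pts = [o.points for o in self.options if o.points is not None]
            sums = {0.0}
            for p in pts:
                sums |= {s + p for s in sums}
            grid = {min(QUESTION_MAX, s) for s in sums if s > 0}
        else:  # pragma: no cover - literal type forbids this
            raise AssertionError(self.aggregation)
        return tuple(sorted(grid))


class SurveySchema(BaseModel):
    """Ordered categories + questions + the participation gate."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    version: str
    gating_question_id: str
    categories: tuple[str, ...]
    questions: tuple[Question, ...]

    def question(self, qid: str) -> Question:
        for q in self.questions:
            if q.id == qid:
                return q
        raise KeyError(f"unknown question id {qid!r}")


@dataclass(frozen=True)
class Violation:
    """One rubric-invariant failure; ``question_id`` is None for global rules."""

    rule: str
    question_id: Optional[str]
    message: str

    def __str__(self) -> str:
        where = f" [{self.question_id}]" if self.question_id else ""
        return f"{self.rule}{where}: {self.message}"


class Rubric:
    """The scoring contract: the schema plus derived per-question score maps.

    ``question_scores`` exposes, for each scored question, its domain, its
    option-code -> points map, and its multi-select aggregation rule.
    """

    def __init__(self, schema: SurveySchema):
        self.schema = schema
        self._by_id = {q.id: q for q in schema.questions}
        self._scored = tuple(q for q in schema.questions if q.scored)

    @property
    def version(self) -> str:
        return self.schema.version

    @property
    def scored_questions(self) -> tuple[Question, ...]:
        return self._scored

    @property
    def question_scores(self) -> dict[str, tuple[str, dict[str, float], str]]:
        return {
            q.id: (
                q.domain,
                {o.code: o.points for o in q.options if o.points is not None},
                q.aggregation,
            )
            for q in self.scored_questions
        }

    def question(self, qid: str) -> Question:
        try:
            return self._by_id[qid]
        except KeyError:
            raise KeyError(f"unknown question id {qid!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, Rubric) and self.schema == other.schema

    def __repr__(self) -> str:
        return f"Rubric(version={self.version!r}, scored={len(self.scored_questions)})"

    def to_dict(self) -> dict:
        return self.schema.model_dump(exclude_none=True, exclude_defaults=True)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)


def _attainable_max(question: Question) -> float:
    grid = question.attainable_points()
    return max(grid) if grid else 0.0


def validate_rubric(rubric: Rubric) -> list[Violation]:
    """Check every rubric invariant; returns violations instead of raising.

    Rules: unique question ids; known categories; gating question exists and
    comes first; scored questions are non-free-text with options, carry one
    of the four domains, exactly five per domain; option points lie in
    [1, 5]; the attainable per-question maximum is exactly 5 under the
    question's aggregation rule (hence 25 per domain).
    """
    v: list[Violation] = []
    schema = rubric.schema

    seen: set[str] = set()
    for q in schema.questions:
        if q.id in seen:
            v.append(Violation("duplicate-id", q.id, "question id appears twice"))
        seen.add(q.id)
        if q.category not in schema.categories:
            v.append(Violation("unknown-category", q.id, f"category {q.category!r}"))
        codes = [o.code for o in q.options]
        if len(codes) != len(set(codes)):
            v.append(Violation("duplicate-option", q.id, "option code appears twice"))

    if schema.gating_question_id not in {q.id for q in schema.questions}:
        v.append(
            Violation(
                "gating-question",
                None,
                f"gating question {schema.gating_question_id!r} not in schema",
            )
        )
    elif schema.questions and schema.questions[0].id != schema.gating_question_id:
        v.append(
            Violation("gating-question", None, "gating question must come first")
        )

    per_domain: dict[str, int] = {d: 0 for d in DOMAINS}
    for q in schema.questions:
        if not q.scored:
            continue
        if q.response_mode == "free-text":
            v.append(Violation("scored-free-text", q.id, "scored question is free-text"))
            continue
        if not q.options:
            v.append(Violation("no-options", q.id, "scored question has no options"))
            continue
        if q.domain not in DOMAINS:
            v.append(Violation("unknown-domain", q.id, f"domain {q.domain!r}"))
            continue
        per_domain[q.domain] += 1

        pointed = [o for o in q.options if o.points is not None]
        if q.aggregation != "count_banded" and len(pointed) != len(q.options):
            v.append(Violation("missing-points", q.id, "option without points"))
        for o in pointed:
            if not 0 <= o.points <= QUESTION_MAX:
                v.append(
                    Violation(
                        "points-range", q.id, f"option {o.code!r} points {o.points}"
                    )
                )
            elif o.points < 1:
                v.append(
                    Violation(
                        "min-points", q.id, f"option {o.code!r} points {o.points} < 1"
                    )
                )
        if q.aggregation == "count_banded" and len(q.options) < QUESTIONS_PER_DOMAIN:
            v.append(
                Violation(
                    "count-banded-options",
                    q.id,
                    "count_banded needs at least 5 options to attain 5 points",
                )
            )
        attainable = _attainable_max(q)
        if attainable != QUESTION_MAX:
            v.append(
                Violation(
                    "question-max",
                    q.id,
                    f"attainable maximum {attainable} != {QUESTION_MAX}",
                )
            )

    for domain, count in per_domain.items():
        if count != QUESTIONS_PER_DOMAIN:
            v.append(
                Violation(
                    "domain-count",
                    None,
                    f"domain {domain} has {count} scored questions, expected 5",
                )
            )
    return v


def validate_schema(schema: SurveySchema) -> list[Violation]:
    """Full-survey shape checks (59 total / 56 required / 3 free-text)."""
    v: list[Violation] = []
    total = len(schema.questions)
    freetext = sum(q.response_mode == "free-text" for q in schema.questions)
    required = total - freetext
    if total != FULL_SURVEY_TOTAL:
        v.append(Violation("survey-total", None, f"{total} questions, expected 59"))
    if required != FULL_SURVEY_REQUIRED:
        v.append(
            Violation("survey-required", None, f"{required} required, expected 56")
        )
    if freetext != FULL_SURVEY_FREETEXT:
        v.append(Violation("survey-freetext", None, f"{freetext} free-text, expected 3"))
    return v


def _parse_schema(raw: dict, source: str) -> SurveySchema:
    try:
        return SurveySchema.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"{source}: invalid survey config: {exc}") from exc


def load_rubric(path: str | Path, *, require_full_survey: bool = False) -> Rubric:
    """Load and validate a rubric config file.

    Raises :class:`ConfigError` on parse failure (with YAML line context) and
    :class:`RubricValidationError` if any invariant is violated. With
    ``require_full_survey`` the 59/56/3 survey-shape checks are enforced too.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc
    return loads_rubric(text, source=str(path), require_full_survey=require_full_survey)


def loads_rubric(
    text: str, *, source: str = "<string>", require_full_survey: bool = False
) -> Rubric:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        ctx = f" (line {mark.line + 1}, column {mark.column + 1})" if mark else ""
        raise ConfigError(f"{source}: YAML parse error{ctx}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    schema = _parse_schema(raw, source)
    rubric = Rubric(schema)
    violations = validate_rubric(rubric)
    if require_full_survey:
        violations += validate_schema(schema)
    if violations:
        raise RubricValidationError(violations)
    return rubric


def reference_rubric() -> Rubric:
    """The shipped ``acte_mtb_v1`` instrument (full 59-question survey)."""
    ref = importlib.resources.files("acte_mtb.data") / "acte_mtb_v1.yaml"
    return loads_rubric(
        ref.read_text(encoding="utf-8"), source="acte_mtb_v1.yaml",
        require_full_survey=True,
    )


def list_scored_questions(rubric: Rubric, domain: str) -> list[str]:
    """Ids of the five scored questions of ``domain``, in schema order."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    return [q.id for q in rubric.scored_questions if q.domain == domain]


def iter_scored(rubric: Rubric, domains: Iterable[str] = DOMAINS):
    for d in domains:
        for qid in list_scored_questions(rubric, d):
            yield rubric.question(qid)
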