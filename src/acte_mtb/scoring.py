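"""Translate survey answers into per-domain points, 0-5 scores and 1-5 levels.

Each scored question is worth at most 5 points. A fully answered domain
(5 questions) attains at most 25 points; the domain maturity score is that
sum divided by 5, i.e. the mean per-question points, on the 0-5 scale. When
a single question of a domain is skipped, the answered sum is rescaled by
5/n_answered before the division — equivalently the score is still the mean
points of the answered questions, so one missing answer does not depress the
score. A literal missing-as-zero reading (sum over 25 regardless) is
available via ``missing_policy="zero"``.

Maturity levels 1-5 band the continuous score at integer boundaries: a score
in ((n-1), n] maps to level n, and everything at or below 1 is level 1.

The overall maturity score is the arithmetic mean of the four domain scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .errors import ScoringError
from .rubric import DOMAINS, QUESTIONS_PER_DOMAIN, Question, Rubric, list_scored_questions

Answer = Union[str, Sequence[str], None]

#: canonical institution types (answer codes of the institution question)
INSTITUTION_TYPES = (
    "academic_medical_center",
    "community_hospital",
    "specialized_cancer_clinic",
    "private_practice",
)


@dataclass
class ResponseRecord:
    """One respondent's answers plus self-reported demographics."""

    respondent_id: str
    answers: dict[str, Answer] = field(default_factory=dict)
    country: Optional[str] = None
    institution_type: Optional[str] = None
    roles: tuple[str, ...] = ()

    def answered(self, qid: str) -> bool:
        a = self.answers.get(qid)
        if a is None:
            return False
        if isinstance(a, str):
            return a != ""
        return len(a) > 0


@dataclass(frozen=True)
class DomainScore:
    domain: str
    points_sum: float
    n_answered: int
    score: float  # NaN when not assessable (no answered question)
    level: Optional[int]

    @property
    def assessable(self) -> bool:
        return not math.isnan(self.score)


@dataclass(frozen=True)
class MaturityAssessment:
    respondent_id: str
    domain_scores: dict[str, DomainScore]
    overall: float
    question_points: dict[str, Optional[float]]
    country: Optional[str] = None
    institution_type: Optional[str] = None

    def score(self, domain: str) -> float:
        return self.domain_scores[domain].score


def _codes(question: Question, answer: Answer) -> list[str]:
    if isinstance(answer, str):
        codes = [answer]
    else:
        codes = list(answer or ())
    if question.response_mode == "single-choice" and len(codes) != 1:
        raise ScoringError(
            f"question {question.id!r} is single-choice but got {len(codes)} codes"
        )
    known = set(question.option_codes)
    for c in codes:
        if c not in known:
            raise ScoringError(f"question {question.id!r}: unknown option code {c!r}")
    return codes


def translate_answer(question: Question, answer: Answer, rubric: Rubric) -> Optional[float]:
    """Points earned by ``answer`` on a scored question; None when unanswered.

    Multi-select answers aggregate per the question's declared rule:
    ``max`` (default) takes the best selected option, ``sum_capped`` sums
    selected option points capped at 5, ``count_banded`` awards
    min(5, number of selections). All rules keep the per-question budget at 5.
    """
    if not question.scored:
        raise ScoringError(f"question {question.id!r} is not scored")
    if answer is None or (not isinstance(answer, str) and len(answer) == 0) or answer == "":
        return None
    codes = _codes(question, answer)
    if question.aggregation == "count_banded":
        return float(min(5, len(codes)))
    pts = []
    for c in codes:
        p = question.option(c).points
        if p is None:
            raise ScoringError(f"question {question.id!r}: option {c!r} has no points")
        pts.append(p)
    if question.aggregation == "sum_capped":
        return float(min(5.0, sum(pts)))
    return float(max(pts))


def level_from_score(score: float) -> int:
    """Band a 0-5 score into maturity level 1-5 (score in ((n-1), n] -> n)."""
    if math.isnan(score) or not 0 <= score <= 5:
        raise ScoringError(f"score {score} outside [0, 5]")
    return max(1, math.ceil(score))


def score_domain(
    record: ResponseRecord,
    rubric: Rubric,
    domain: str,
    *,
    missing_policy: str = "rescale",
    strict: bool = False,
) -> DomainScore:
    """Score one ACTE domain for one respondent.

    With ``a`` of the five questions answered, ``rescale`` (default) gives
    score = points_sum * (5/a) / 5 = mean per-question points; ``zero``
    keeps the literal 25-point denominator (score = points_sum / 5). With no
    answered question the domain is not assessable: error in strict mode,
    NaN score otherwise.
    """
    if missing_policy not in ("rescale", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    qids = list_scored_questions(rubric, domain)
    points = []
    for qid in qids:
        p = translate_answer(rubric.question(qid), record.answers.get(qid), rubric)
        if p is not None:
            points.append(p)
    n_answered = len(points)
    points_sum = float(sum(points))
    if n_answered == 0:
        if strict:
            raise ScoringError(
                f"respondent {record.respondent_id!r}: domain {domain} has no "
                "answered scored question"
            )
        return DomainScore(domain, 0.0, 0, float("nan"), None)
    if missing_policy == "rescale":
        normalized = points_sum * (QUESTIONS_PER_DOMAIN / n_answered)
    else:
        normalized = points_sum
    score = normalized / QUESTIONS_PER_DOMAIN
    return DomainScore(domain, points_sum, n_answered, score, level_from_score(score))


def assess(
    record: ResponseRecord,
    rubric: Rubric,
    *,
    missing_policy: str = "rescale",
    strict: bool = False,
) -> MaturityAssessment:
    """Full maturity assessment: four domain scores + overall mean.

    The overall score is the arithmetic mean of the four domain scores,
    carried at full floating precision (rounding happens only at reporting).
    NaN-propagates when a domain is not assessable in permissive mode.
    """
    domain_scores: dict[str, DomainScore] = {}
    failed = []
    for d in DOMAINS:
        ds = score_domain(record, rubric, d, missing_policy=missing_policy)
        if not ds.assessable:
            failed.append(d)
        domain_scores[d] = ds
    if failed and strict:
        raise ScoringError(
            f"respondent {record.respondent_id!r}: domains not assessable: "
            + ", ".join(failed)
        )
    overall = sum(ds.score for ds in domain_scores.values()) / len(DOMAINS)

    question_points: dict[str, Optional[float]] = {}
    for q in rubric.scored_questions:
        question_points[q.id] = translate_answer(q, record.answers.get(q.id), rubric)

    return MaturityAssessment(
        respondent_id=record.respondent_id,
        domain_scores=domain_scores,
        overall=overall,
        question_points=question_points,
        country=record.country,
        institution_type=record.institution_type,
    )


def score_cohort(
    records: Sequence[ResponseRecord],
    rubric: Rubric,
    *,
    missing_policy: str = "rescale",
    strict: bool = False,
) -> list[MaturityAssessment]:
    """Assess every record, order-preserving; aggregates per-record errors."""
    out = []
    errors = []
    for rec in records:
        try:
            out.append(assess(rec, rubric, missing_policy=missing_policy, strict=strict))
        except ScoringError as exc:
            errors.append(f"{rec.respondent_id}: {exc}")
    if errors:
        raise ScoringError("cohort scoring failed for: " + "; ".join(errors))
    return out
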