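"""Shared fixtures: the shipped instrument, the validation score table, and
programmatic toy rubrics for engine-level and property tests."""

from __future__ import annotations

import pytest

from acte_mtb import (
    DOMAINS,
    AnswerOption,
    Question,
    ResponseRecord,
    Rubric,
    SurveySchema,
    load_table4_fixture,
    reference_rubric,
)


@pytest.fixture(scope="session")
def rubric() -> Rubric:
    return reference_rubric()


@pytest.fixture(scope="session")
def table4():
    return load_table4_fixture()


def build_rubric(grids: list[list[float]], version: str = "toy") -> Rubric:
    """A minimal valid rubric: 20 single-choice scored questions (5 per
    domain) whose option point values are given by ``grids`` (each grid must
    contain 5.0 and stay within [1, 5])."""
    assert len(grids) == 20
    questions = [
        Question(
            id="gate",
            text="Participate?",
            category="General",
            response_mode="single-choice",
            options=(
                AnswerOption(code="yes", label="Yes"),
                AnswerOption(code="no", label="No"),
            ),
        )
    ]
    k = 0
    for domain in DOMAINS:
        for i in range(5):
            grid = sorted(set(grids[k]))
            questions.append(
                Question(
                    id=f"{domain.lower()}_q{i + 1}",
                    text=f"{domain} question {i + 1}",
                    category="General",
                    response_mode="single-choice",
                    scored=True,
                    domain=domain,
                    options=tuple(
                        AnswerOption(code=f"o{j}", label=f"option {j}", points=p)
                        for j, p in enumerate(grid)
                    ),
                )
            )
            k += 1
    schema = SurveySchema(
        version=version,
        gating_question_id="gate",
        categories=("General",),
        questions=tuple(questions),
    )
    return Rubric(schema)


@pytest.fixture()
def toy_rubric() -> Rubric:
    """All 20 scored questions on the plain 1..5 integer grid."""
    return build_rubric([[1.0, 2.0, 3.0, 4.0, 5.0]] * 20)


def record_with_points(rubric: Rubric, points: dict[str, float],
                       respondent_id: str = "r1") -> ResponseRecord:
    """A record answering each given scored question at the option worth the
    requested point value (options must exist at exactly those values)."""
    answers: dict = {"gate": "yes"}
    for qid, target in points.items():
        q = rubric.question(qid)
        code = next(o.code for o in q.options if o.points == target)
        answers[qid] = code
    return ResponseRecord(respondent_id=respondent_id, answers=answers)
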