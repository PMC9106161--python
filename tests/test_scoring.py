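"""Answer translation, domain normalization, level banding, assessments."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acte_mtb import (
    DOMAINS,
    ResponseRecord,
    ScoringError,
    assess,
    level_from_score,
    score_cohort,
    score_domain,
    translate_answer,
)

from conftest import build_rubric, record_with_points


# sorted point grids containing the 5-point top option, all >= 1
grid_strategy = st.lists(
    st.floats(1.0, 4.75, allow_nan=False, allow_infinity=False),
    min_size=0, max_size=4, unique=True,
).map(lambda xs: sorted(set(round(x * 4) / 4 for x in xs) | {5.0}))

rubric_strategy = st.lists(grid_strategy, min_size=20, max_size=20).map(build_rubric)


class TestTranslateAnswer:
    def test_top_option_of_every_scored_question_is_worth_five(self, rubric):
        for q in rubric.scored_questions:
            if q.aggregation == "count_banded":
                answer = list(q.option_codes)[:5]
            elif q.aggregation == "sum_capped":
                answer = list(q.option_codes)
            else:
                best = max((o for o in q.options), key=lambda o: o.points)
                answer = best.code if q.response_mode == "single-choice" else [best.code]
            assert translate_answer(q, answer, rubric) == 5.0

    def test_implementation_rate_top_band(self, rubric):
        q = rubric.question("implementation_rate")
        assert translate_answer(q, "76_100", rubric) == 5.0

    def test_multiselect_max_rule(self, rubric):
        q = rubric.question("test_types_discussed")  # max rule, points 1..5
        assert translate_answer(q, ["single_gene", "large_panel"], rubric) == 4.0

    def test_multiselect_sum_capped(self, rubric):
        q = rubric.question("structured_documentation")  # 1.5 + 2 = 3.5
        assert translate_answer(q, ["recommendations", "outcomes"], rubric) == 3.5
        assert translate_answer(q, list(q.option_codes), rubric) == 5.0  # capped

    def test_multiselect_count_banded(self, rubric):
        q = rubric.question("mtb_roles_present")
        assert translate_answer(q, ["oncology"], rubric) == 1.0
        assert translate_answer(q, list(q.option_codes)[:7], rubric) == 5.0  # capped

    def test_unanswered_is_missing_not_zero(self, rubric):
        q = rubric.question("implementation_rate")
        assert translate_answer(q, None, rubric) is None
        assert translate_answer(q, "", rubric) is None
        assert translate_answer(q, [], rubric) is None

    def test_unknown_code_names_question_and_code(self, rubric):
        q = rubric.question("implementation_rate")
        with pytest.raises(ScoringError, match="implementation_rate.*bogus"):
            translate_answer(q, "bogus", rubric)

    def test_single_choice_rejects_multiple_codes(self, rubric):
        q = rubric.question("implementation_rate")
        with pytest.raises(ScoringError, match="single-choice"):
            translate_answer(q, ["0_25", "26_50"], rubric)


class TestLevelFromScore:
    @pytest.mark.parametrize(
        "score,level",
        [(5.0, 5), (2.6, 3), (0.0, 1), (1.0, 1), (3.0, 3), (4.001, 5), (0.5, 1)],
    )
    def test_banding(self, score, level):
        assert level_from_score(score) == level

    @pytest.mark.parametrize("score", [-0.1, 5.1, float("nan")])
    def test_out_of_range(self, score):
        with pytest.raises(ScoringError):
            level_from_score(score)


class TestScoreDomain:
    def test_maximum(self, toy_rubric):
        rec = record_with_points(
            toy_rubric, {f"access_q{i}": 5.0 for i in range(1, 6)}
        )
        ds = score_domain(rec, toy_rubric, "Access")
        assert (ds.points_sum, ds.score, ds.level) == (25.0, 5.0, 5)

    def test_hand_arithmetic(self, toy_rubric):
        pts = dict(zip([f"access_q{i}" for i in range(1, 6)], [1, 2, 3, 3, 4]))
        ds = score_domain(record_with_points(toy_rubric, pts), toy_rubric, "Access")
        assert ds.points_sum == 13.0
        assert ds.score == pytest.approx(2.6)
        assert ds.level == 3

    def test_missing_answer_rescaled(self, toy_rubric):
        # 4 of 5 answered with 5,5,4,4: normalized 18 * 5/4 = 22.5 -> 4.5
        pts = dict(zip([f"access_q{i}" for i in range(1, 5)], [5, 5, 4, 4]))
        ds = score_domain(record_with_points(toy_rubric, pts), toy_rubric, "Access")
        assert ds.n_answered == 4
        assert ds.score == pytest.approx(4.5)

    def test_missing_as_zero_policy(self, toy_rubric):
        pts = dict(zip([f"access_q{i}" for i in range(1, 5)], [5, 5, 4, 4]))
        rec = record_with_points(toy_rubric, pts)
        ds = score_domain(rec, toy_rubric, "Access", missing_policy="zero")
        assert ds.score == pytest.approx(18 / 5)

    def test_empty_domain_flagged_or_strict_error(self, toy_rubric):
        rec = ResponseRecord(respondent_id="r", answers={"gate": "yes"})
        ds = score_domain(rec, toy_rubric, "Access")
        assert not ds.assessable and ds.level is None
        with pytest.raises(ScoringError, match="Access"):
            score_domain(rec, toy_rubric, "Access", strict=True)


class TestAssess:
    def test_all_maximum_gives_overall_five(self, toy_rubric):
        pts = {q.id: 5.0 for q in toy_rubric.scored_questions}
        a = assess(record_with_points(toy_rubric, pts), toy_rubric)
        assert a.overall == 5.0
        assert all(ds.level == 5 for ds in a.domain_scores.values())

    def test_overall_is_mean_of_domains(self, toy_rubric):
        # domain means 3.9ish pattern: engineer exact per-domain scores
        per_domain = {"Access": 3.0, "Consultation": 4.0, "Technology": 5.0, "Evidence": 2.0}
        pts = {}
        for d, s in per_domain.items():
            for i in range(1, 6):
                pts[f"{d.lower()}_q{i}"] = s
        a = assess(record_with_points(toy_rubric, pts), toy_rubric)
        assert a.overall == pytest.approx(3.5)
        for d, s in per_domain.items():
            assert a.domain_scores[d].score == pytest.approx(s)

    def test_question_points_map_covers_all_scored(self, toy_rubric):
        pts = {q.id: 5.0 for q in toy_rubric.scored_questions}
        del pts["access_q1"]
        a = assess(record_with_points(toy_rubric, pts), toy_rubric)
        assert len(a.question_points) == 20
        assert a.question_points["access_q1"] is None

    def test_strict_mode_lists_unassessable_domains(self, toy_rubric):
        rec = record_with_points(
            toy_rubric, {f"access_q{i}": 5.0 for i in range(1, 6)}
        )
        with pytest.raises(ScoringError, match="Consultation.*Technology.*Evidence"):
            assess(rec, toy_rubric, strict=True)


class TestScoreCohort:
    def test_empty(self, toy_rubric):
        assert score_cohort([], toy_rubric) == []

    def test_order_preserved_under_permutation(self, toy_rubric):
        rng = random.Random(0)
        recs = [
            record_with_points(
                toy_rubric,
                {q.id: float(rng.randint(1, 5)) for q in toy_rubric.scored_questions},
                respondent_id=f"r{i}",
            )
            for i in range(12)
        ]
        direct = score_cohort(recs, toy_rubric)
        perm = list(recs)
        rng.shuffle(perm)
        permuted = score_cohort(perm, toy_rubric)
        by_id = {a.respondent_id: a for a in permuted}
        assert [a.respondent_id for a in direct] == [r.respondent_id for r in recs]
        for a in direct:
            assert by_id[a.respondent_id].overall == a.overall


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(rubric=rubric_strategy, data=st.data())
    def test_monotone_under_answer_upgrade(self, rubric, data):
        """Swapping any answer for an option worth >= points never lowers
        any domain score or the overall score."""
        choices = {}
        for q in rubric.scored_questions:
            idx = data.draw(st.integers(0, len(q.options) - 1), label=q.id)
            choices[q.id] = q.options[idx]
        rec = ResponseRecord("r", answers={qid: o.code for qid, o in choices.items()})
        base = assess(rec, rubric)

        target = data.draw(
            st.sampled_from([q.id for q in rubric.scored_questions]), label="upgraded"
        )
        q = rubric.question(target)
        better = [o for o in q.options if o.points >= choices[target].points]
        up = data.draw(st.sampled_from(better), label="upgrade_option")
        rec2 = ResponseRecord("r", answers={**rec.answers, target: up.code})
        upgraded = assess(rec2, rubric)

        assert upgraded.overall >= base.overall - 1e-12
        for d in DOMAINS:
            assert upgraded.domain_scores[d].score >= base.domain_scores[d].score - 1e-12

    @settings(max_examples=60, deadline=None)
    @given(rubric=rubric_strategy, data=st.data())
    def test_overall_mean_identity_and_missing_normalization(self, rubric, data):
        """Overall equals the mean of the four domain scores to machine
        precision, and each domain score equals the mean per-question points
        of its answered questions."""
        answers = {}
        expected_points = {}
        for q in rubric.scored_questions:
            idx = data.draw(st.integers(-1, len(q.options) - 1), label=q.id)
            if idx < 0:
                answers[q.id] = None
            else:
                answers[q.id] = q.options[idx].code
                expected_points[q.id] = q.options[idx].points
        # keep every domain assessable
        for d in DOMAINS:
            ids = [q.id for q in rubric.scored_questions if q.domain == d]
            if not any(answers[i] is not None for i in ids):
                q = rubric.question(ids[0])
                answers[ids[0]] = q.options[-1].code
                expected_points[ids[0]] = q.options[-1].points

        a = assess(ResponseRecord("r", answers=answers), rubric)
        domain_scores = [a.domain_scores[d].score for d in DOMAINS]
        assert a.overall == sum(domain_scores) / 4  # exact float identity
        for d in DOMAINS:
            pts = [
                expected_points[q.id]
                for q in rubric.scored_questions
                if q.domain == d and answers[q.id] is not None
            ]
            assert a.domain_scores[d].score == pytest.approx(
                sum(pts) / len(pts), abs=1e-12
            )
            assert 1.0 - 1e-12 <= a.domain_scores[d].score <= 5.0 + 1e-12

    @settings(max_examples=30, deadline=None)
    @given(rubric=rubric_strategy, seed=st.integers(0, 2**16))
    def test_invariant_to_answer_ordering(self, rubric, seed):
        rng = random.Random(seed)
        items = [
            (q.id, rng.choice(q.options).code) for q in rubric.scored_questions
        ]
        a1 = assess(ResponseRecord("r", answers=dict(items)), rubric)
        rng.shuffle(items)
        a2 = assess(ResponseRecord("r", answers=dict(items)), rubric)
        assert a1.overall == a2.overall
        assert all(
            a1.domain_scores[d].score == a2.domain_scores[d].score for d in DOMAINS
        )

    def test_fully_answered_score_is_points_over_five(self, toy_rubric):
        pts = dict(zip([f"evidence_q{i}" for i in range(1, 6)], [2, 3, 1, 5, 4]))
        ds = score_domain(record_with_points(toy_rubric, pts), toy_rubric, "Evidence")
        assert ds.score == pytest.approx(15 / 5)
        assert math.isclose(ds.score, ds.points_sum / 5)
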