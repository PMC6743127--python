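"""Scoring engine: scheme validation, item/box scoring, GUS totals."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from dpi_usability.devices import GROUP_DEVICES
from dpi_usability.errors import (
    DesignViolationError,
    InvalidSchemeError,
    MissingAnswerError,
)
from dpi_usability.scoring import (
    BoxScheme,
    ItemRule,
    QuestionnaireResponse,
    ScoringScheme,
    best_answers,
    compute_gus,
    default_scheme,
    score_box,
    score_item,
    score_measurement,
    validate_scheme,
    worst_answers,
)


def scheme_with_box_maxima(maxima):
    """A minimal scheme whose five boxes carry one categorical item each."""
    boxes = tuple(
        BoxScheme(
            box_id=i + 1,
            items=(ItemRule(f"item{i}", "categorical", {"best": m, "worst": 0}),),
            max_points=m,
        )
        for i, m in enumerate(maxima)
    )
    return ScoringScheme(version="test", boxes=boxes)


class TestValidateScheme:
    def test_default_scheme_accepted(self, scheme):
        assert validate_scheme(scheme) is scheme

    def test_box_maxima_not_summing_to_50_rejected(self):
        with pytest.raises(InvalidSchemeError, match="45"):
            validate_scheme(scheme_with_box_maxima([10, 10, 10, 10, 5]))

    def test_non_monotone_time_mapping_rejected(self, scheme):
        # award more points to a slower time: monotonicity violation
        bad_time = ItemRule(
            "seconds_to_autonomy",
            "time-threshold",
            ((0.0, 60.0, 4), (60.0, 120.0, 10), (120.0, None, 0)),
        )
        boxes = list(scheme.boxes)
        boxes[3] = BoxScheme(4, (bad_time,), 10)
        with pytest.raises(InvalidSchemeError, match="non-increasing"):
            validate_scheme(ScoringScheme("bad", tuple(boxes)))

    def test_interval_gap_rejected(self, scheme):
        gappy = ItemRule(
            "critical_issues",
            "count-threshold",
            ((0.0, 1.0, 10), (2.0, None, 0)),  # nothing covers [1, 2)
        )
        boxes = list(scheme.boxes)
        boxes[1] = BoxScheme(2, (gappy,), 10)
        with pytest.raises(InvalidSchemeError, match="partition"):
            validate_scheme(ScoringScheme("bad", tuple(boxes)))

    def test_wrong_box_count_rejected(self, scheme):
        with pytest.raises(InvalidSchemeError, match="5 boxes"):
            validate_scheme(ScoringScheme("bad", scheme.boxes[:4]))

    def test_json_round_trip(self, scheme, tmp_path):
        path = tmp_path / "scheme.json"
        scheme.to_json(path)
        loaded = ScoringScheme.from_json(path)
        assert validate_scheme(loaded) == scheme


class TestScoreMeasurement:
    @pytest.fixture()
    def attempts_rule(self, scheme):
        return scheme.box(3).items[0]

    def test_one_attempt_scores_item_maximum(self, attempts_rule):
        assert score_measurement(1, attempts_rule) == attempts_rule.max_points

    def test_boundary_value_belongs_to_upper_interval(self, attempts_rule):
        # intervals are half-open [lo, hi): 2 attempts fall in [2, 3)
        assert score_measurement(2, attempts_rule) == 7
        assert score_measurement(1.999, attempts_rule) == 10

    def test_negative_value_rejected(self, attempts_rule):
        with pytest.raises(ValueError, match="negative"):
            score_measurement(-1, attempts_rule)

    def test_monotone_non_increasing_over_all_rules(self, scheme):
        # exhaustive check at every interval edge and interior point
        for rule in scheme.items:
            if rule.kind == "categorical":
                continue
            probes = []
            for lo, hi, _ in rule.intervals:
                probes.append(lo)
                probes.append(lo + 0.5 if hi is None else (lo + hi) / 2)
            probes.sort()
            points = [score_measurement(v, rule) for v in probes]
            assert points == sorted(points, reverse=True), rule.item_id


class TestScoreBox:
    def test_all_best_answers_reach_box_maximum(self, scheme):
        answers = best_answers(scheme)
        for box in scheme.boxes:
            assert score_box(answers, box) == box.max_points

    def test_all_worst_answers_score_zero(self, scheme):
        answers = worst_answers(scheme)
        for box in scheme.boxes:
            assert score_box(answers, box) == 0

    def test_mixed_answers_equal_hand_summation(self, scheme):
        answers = best_answers(scheme)
        answers["critical_issues"] = 2        # 4 points under the default rule
        answers["closed_q03"] = "no"          # 0 points
        box5 = scheme.box(5)
        by_hand = sum(score_item(answers[it.item_id], it) for it in box5.items)
        assert score_box(answers, box5) == by_hand == 9
        assert score_box(answers, scheme.box(2)) == 4

    def test_missing_answer_raises_identifying_item(self, scheme):
        answers = best_answers(scheme)
        del answers["closed_q07"]
        with pytest.raises(MissingAnswerError, match="closed_q07"):
            score_box(answers, scheme.box(5), context="respondent R1, device Ellipta")


class TestComputeGUS:
    def test_best_possible_response_scores_fifty(self, scheme):
        resp = QuestionnaireResponse(
            "R1", "experienced", 3,
            {"Breezhaler": best_answers(scheme), "Genuair": best_answers(scheme)},
        )
        records = compute_gus(resp, scheme)
        assert [r.gus_total for r in records] == [50, 50]

    def test_worst_possible_response_scores_zero(self, scheme):
        resp = QuestionnaireResponse(
            "R1", "naive", 3, {"Breezhaler": worst_answers(scheme)}
        )
        (rec,) = compute_gus(resp, scheme)
        assert rec.gus_total == 0 and rec.subscores == (0, 0, 0, 0, 0)

    def test_group3_respondent_yields_two_records(self, scheme):
        resp = QuestionnaireResponse(
            "R9", "experienced", 3,
            {"Genuair": best_answers(scheme), "Breezhaler": best_answers(scheme)},
        )
        records = compute_gus(resp, scheme)
        assert {r.device for r in records} == {"Breezhaler", "Genuair"}
        assert len(records) == 2

    def test_device_outside_group_set_rejected(self, scheme):
        assert "Ellipta" not in GROUP_DEVICES[3]
        resp = QuestionnaireResponse(
            "R1", "experienced", 3, {"Ellipta": best_answers(scheme)}
        )
        with pytest.raises(DesignViolationError, match="Ellipta"):
            compute_gus(resp, scheme)

    def test_device_name_normalization(self, scheme):
        resp = QuestionnaireResponse(
            "R1", "experienced", 2, {" diskus ": best_answers(scheme)}
        )
        (rec,) = compute_gus(resp, scheme)
        assert rec.device == "Diskus"


# -- property tests ---------------------------------------------------------

def _random_answers(draw, scheme):
    answers = {}
    for it in scheme.items:
        if it.kind == "categorical":
            answers[it.item_id] = draw(st.sampled_from(sorted(it.mapping)))
        else:
            lo0 = it.intervals[0][0]
            answers[it.item_id] = draw(
                st.floats(min_value=lo0, max_value=600.0, allow_nan=False)
            )
    return answers


@settings(max_examples=30, deadline=None)
@given(data=st.data())
def test_total_is_sum_of_subscores_and_bounded(data):
    scheme = default_scheme()
    answers = _random_answers(data.draw, scheme)
    resp = QuestionnaireResponse("R1", "experienced", 1, {"Ellipta": answers})
    (rec,) = compute_gus(resp, scheme)
    assert rec.gus_total == sum(rec.subscores)
    assert 0 <= rec.gus_total <= 50


@settings(max_examples=15, deadline=None)
@given(data=st.data())
def test_scoring_is_permutation_invariant_in_device_order(data):
    scheme = default_scheme()
    a1 = _random_answers(data.draw, scheme)
    a2 = _random_answers(data.draw, scheme)
    fwd = QuestionnaireResponse("R1", "naive", 3, {"Breezhaler": a1, "Genuair": a2})
    rev = QuestionnaireResponse("R1", "naive", 3, {"Genuair": a2, "Breezhaler": a1})
    assert compute_gus(fwd, scheme) == compute_gus(rev, scheme)


def test_improving_any_single_item_never_decreases_total(scheme):
    # exhaustive single-item perturbation from the worst-possible response
    base = worst_answers(scheme)
    base_total = sum(score_box(base, b) for b in scheme.boxes)
    for it in scheme.items:
        better = dict(base)
        better[it.item_id] = it.best_answer()
        total = sum(score_box(better, b) for b in scheme.boxes)
        assert total >= base_total, it.item_id
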