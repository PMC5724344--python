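"""Relevance metrics and questionnaire scoring."""

import pytest
from hypothesis import given, strategies as st

from ctsearch.evalmetrics import (
    RelevanceMarking,
    SUSResponse,
    USEResponse,
    append_markings,
    at_least_one_relevant_rate,
    load_markings,
    load_sus_responses,
    load_use_responses,
    mean_precision_at_k,
    pooled_precision_at_k,
    precision_at_k,
    study_level_precision_at_k,
    sus_score,
    use_summary,
)


def markings(flags, study_ids=None, query_id="q"):
    return [
        RelevanceMarking(
            session_id="s1",
            query_id=query_id,
            result_id=f"r{i}",
            rank=i,
            relevant=flag,
            study_id=None if study_ids is None else study_ids[i - 1],
        )
        for i, flag in enumerate(flags, start=1)
    ]


class TestPrecisionAtK:
    def test_seven_of_ten(self):
        flags = [True, True, False, True, False, True, True, False, True, True]
        assert precision_at_k(markings(flags), 10) == pytest.approx(0.7)

    def test_all_relevant(self):
        assert precision_at_k(markings([True] * 10), 10) == 1.0

    def test_short_result_list_uses_returned_count(self):
        flags = [True, True, True, True, False]
        assert precision_at_k(markings(flags), 10) == pytest.approx(0.8)

    def test_no_results_is_undefined(self):
        assert precision_at_k([], 10) is None

    def test_gap_in_ranks_rejected(self):
        bad = markings([True, False, True])
        bad = [bad[0], bad[2]]  # skipped rank 2
        with pytest.raises(ValueError, match="gaps"):
            precision_at_k(bad, 10)

    @given(st.lists(st.booleans(), min_size=1, max_size=15),
           st.integers(1, 12))
    def test_flipping_a_top_k_marking_to_relevant_never_decreases(self, flags, k):
        base = precision_at_k(markings(flags), k)
        for i in range(min(k, len(flags))):
            flipped = list(flags)
            flipped[i] = True
            assert precision_at_k(markings(flipped), k) >= base

    @given(st.lists(st.booleans(), min_size=1, max_size=15), st.integers(1, 12))
    def test_bounded_in_unit_interval(self, flags, k):
        value = precision_at_k(markings(flags), k)
        assert 0.0 <= value <= 1.0


class TestAggregation:
    def test_mean(self):
        assert mean_precision_at_k([1.0, 0.5]) == pytest.approx(0.75)

    def test_single_query(self):
        assert mean_precision_at_k([0.3]) == pytest.approx(0.3)

    def test_undefined_queries_excluded(self):
        assert mean_precision_at_k([None, 0.5]) == pytest.approx(0.5)

    def test_no_defined_queries_rejected(self):
        with pytest.raises(ValueError):
            mean_precision_at_k([None])

    def test_pooled_differs_from_mean(self):
        queries = [
            markings([True] * 7 + [False] * 3),
            markings([True] * 9 + [False]),
        ]
        assert pooled_precision_at_k(queries, 10) == pytest.approx(16 / 20)


class TestAtLeastOneRelevantRate:
    def test_fourteen_of_fifteen_rounds_to_93(self):
        queries = [markings([True, False])] * 14 + [markings([False, False])]
        rounded, raw = at_least_one_relevant_rate(queries)
        assert rounded == 93
        assert raw == pytest.approx(1400 / 15)

    def test_all_successful(self):
        assert at_least_one_relevant_rate([markings([True])] * 4)[0] == 100

    def test_none_successful(self):
        assert at_least_one_relevant_rate([markings([False])] * 4)[0] == 0

    @given(st.lists(st.lists(st.booleans(), min_size=1, max_size=5),
                    min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_invariant_to_query_order(self, flag_sets, rnd):
        queries = [markings(flags) for flags in flag_sets]
        shuffled = list(queries)
        rnd.shuffle(shuffled)
        assert at_least_one_relevant_rate(queries) == at_least_one_relevant_rate(shuffled)


class TestStudyLevelPrecision:
    def test_ten_images_two_studies(self):
        flags = [True] * 5 + [False] * 5
        ids = ["A"] * 5 + ["B"] * 5
        assert study_level_precision_at_k(markings(flags, ids), 2) == pytest.approx(0.5)

    def test_every_study_with_a_relevant_image(self):
        flags = [False, True, True, False]
        ids = ["A", "A", "B", "B"]
        assert study_level_precision_at_k(markings(flags, ids), 10) == 1.0

    def test_any_relevant_rule_per_study(self):
        flags = [False] * 5 + [True, False] + [False]
        ids = ["A"] * 5 + ["B", "B"] + ["C"]
        assert study_level_precision_at_k(markings(flags, ids), 3) == pytest.approx(1 / 3)

    def test_missing_study_id_rejected(self):
        with pytest.raises(ValueError, match="study_id"):
            study_level_precision_at_k(markings([True]), 10)


class TestSUS:
    def test_mixed_response_scores_77_5(self):
        resp = SUSResponse("r1", (4, 1, 4, 2, 4, 2, 4, 2, 4, 2))
        assert sus_score(resp) == pytest.approx(77.5)

    def test_best_possible_scores_100(self):
        resp = SUSResponse("r1", (5, 1, 5, 1, 5, 1, 5, 1, 5, 1))
        assert sus_score(resp) == pytest.approx(100.0)

    def test_all_neutral_scores_50(self):
        assert sus_score(SUSResponse("r1", (3,) * 10)) == pytest.approx(50.0)

    @pytest.mark.parametrize("items", [(3,) * 9, (3,) * 11, (0,) + (3,) * 9,
                                       (6,) + (3,) * 9])
    def test_invalid_responses_rejected(self, items):
        with pytest.raises(ValueError):
            SUSResponse("r1", items)

    @given(st.tuples(*[st.integers(1, 5)] * 10))
    def test_matches_direct_formula(self, items):
        expected = 2.5 * sum(
            (v - 1) if i % 2 == 1 else (5 - v)
            for i, v in enumerate(items, start=1)
        )
        assert sus_score(SUSResponse("r", items)) == expected
        assert 0.0 <= expected <= 100.0


class TestUSE:
    @staticmethod
    def response(values, rid="r1"):
        items = tuple(values) + (None,) * (30 - len(values))
        return USEResponse(rid, items)

    def test_uniform_sixes(self):
        summary = use_summary([self.response([6] * 30)])
        assert summary["overall_median"] == 6
        assert set(summary["per_dimension_median"].values()) == {6}

    def test_na_dropped_before_median(self):
        summary = use_summary([self.response([7, 7, 3])])
        assert summary["per_respondent_median"]["r1"] == 7

    def test_even_count_median_is_mean_of_central_pair(self):
        summary = use_summary([self.response([2, 4, 6, 6])])
        assert summary["per_respondent_median"]["r1"] == pytest.approx(5.0)

    def test_all_na_respondent_excluded_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            summary = use_summary(
                [self.response([6, 6]), USEResponse("r2", (None,) * 30)]
            )
        assert "r2" in caplog.text
        assert list(summary["per_respondent_median"]) == ["r1"]

    def test_every_respondent_na_rejected(self):
        with pytest.raises(ValueError):
            use_summary([USEResponse("r1", (None,) * 30)])

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValueError):
            USEResponse("r1", (8,) + (None,) * 29)


class TestPersistence:
    def test_markings_append_and_reload(self, tmp_path):
        path = tmp_path / "markings.csv"
        first = markings([True, False], ["A", "B"], query_id="q1")
        second = markings([False], ["C"], query_id="q2")
        append_markings(first, path)
        append_markings(second, path)
        grouped = load_markings(path)
        assert set(grouped) == {("s1", "q1"), ("s1", "q2")}
        back = grouped[("s1", "q1")]
        assert [(m.rank, m.relevant, m.study_id) for m in back] == [
            (1, True, "A"), (2, False, "B"),
        ]

    def test_sus_csv_round_trip(self, tmp_path):
        path = tmp_path / "sus.csv"
        header = "respondent_id," + ",".join(f"item_{i}" for i in range(1, 11))
        path.write_text(header + "\nr1,4,1,4,2,4,2,4,2,4,2\n")
        responses = load_sus_responses(path)
        assert sus_score(responses[0]) == pytest.approx(77.5)

    def test_use_csv_round_trip_with_na(self, tmp_path):
        path = tmp_path / "use.csv"
        header = "respondent_id," + ",".join(f"item_{i}" for i in range(1, 31))
        row = "r1," + ",".join(["6"] * 10 + ["NA"] * 20)
        path.write_text(header + "\n" + row + "\n")
        responses = load_use_responses(path)
        assert responses[0].items[:10] == (6,) * 10
        assert responses[0].items[10:] == (None,) * 20
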