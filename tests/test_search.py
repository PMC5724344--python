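"""Text / image / combined search ranking, caps, filters — vs linear-scan oracles."""

import numpy as np
import pytest

import ctsearch as cs
from ctsearch.index import build_initial_index
from ctsearch.search import Filters, apply_filters, combined_search, image_search, text_search

from conftest import small_config
from oracles import combined_rank, image_rank, text_rank
from test_index import toy_study


class TestTextSearch:
    def test_absent_stem_returns_empty_page(self, indexed20, small_cfg):
        _s, _t, _v, idx = indexed20
        page = text_search(idx, "xylophone", config=small_cfg)
        assert len(page) == 0

    def test_ranking_matches_linear_scan(self, indexed20, small_cfg):
        studies, _t, _v, idx = indexed20
        for phrase in ("haemorrhage", "acute haemorrhage infarct",
                       "calcification basal ganglia", "normal appearances"):
            page = text_search(idx, phrase, config=small_cfg)
            expected = text_rank(studies, phrase, small_cfg)
            assert [(s.study_id, s.text_score) for s in page.studies] == expected

    def test_all_stem_match_outranks_partial(self, small_cfg):
        corpus = [
            toy_study("A", "Acute haemorrhage with midline shift."),
            toy_study("B", "Chronic haemorrhage noted."),
            toy_study("C", "Midline structures intact."),
        ]
        _v, idx = build_initial_index(corpus, small_cfg)
        page = text_search(idx, "haemorrhage midline", config=small_cfg)
        assert page.study_ids()[0] == "A"
        assert page.studies[0].text_score == 2
        assert {s.study_id for s in page.studies[1:]} == {"B", "C"}

    def test_uniform_weighting_ignores_which_stems_match(self, small_cfg):
        corpus = [
            toy_study("A", "haemorrhage present"),
            toy_study("B", "infarct present"),
        ]
        _v, idx = build_initial_index(corpus, small_cfg)
        page = text_search(idx, "haemorrhage infarct", config=small_cfg)
        assert [s.text_score for s in page.studies] == [1, 1]

    def test_cap_applied_after_filters(self, small_cfg):
        corpus = [toy_study(f"S{i:02d}", "haemorrhage seen here") for i in range(8)]
        cfg = small_config(max_studies=5)
        _v, idx = build_initial_index(corpus, cfg)
        page = text_search(idx, "haemorrhage", config=cfg)
        assert len(page) == 5

    def test_empty_phrase_rejected(self, indexed20):
        _s, _t, _v, idx = indexed20
        with pytest.raises(ValueError, match="empty query"):
            text_search(idx, "?!.")


class TestImageSearch:
    def test_self_query_ranks_own_study_first(self, indexed20, small_cfg):
        studies, _t, vocab, idx = indexed20
        for study in studies[:6]:
            page = image_search(idx, vocab, study.slices[0], config=small_cfg)
            assert page.study_ids()[0] == study.study_id

    def test_ranking_matches_linear_scan(self, indexed20, small_cfg):
        studies, _t, vocab, idx = indexed20
        query = studies[3].slices[1]
        page = image_search(idx, vocab, query, config=small_cfg)
        expected = image_rank(studies, vocab, query, small_cfg)
        assert [
            (s.study_id, s.image_score, s.shown_images) for s in page.studies
        ] == expected

    def test_roi_query_matches_linear_scan(self, indexed20, small_cfg):
        studies, _t, vocab, idx = indexed20
        query = studies[5].slices[0]
        roi = (16, 48, 16, 48)
        page = image_search(idx, vocab, query, roi=roi, config=small_cfg)
        expected = image_rank(studies, vocab, query, small_cfg, roi=roi)
        assert [(s.study_id, s.image_score) for s in page.studies] == [
            (sid, score) for sid, score, _ in expected
        ]

    def test_shown_images_capped_at_five(self, small_cfg):
        img = cs.generate_study(
            cs.PhantomSpec(seed=77, lesion_class="infarct", image_size=64, n_slices=1)
        ).slices[0]
        corpus = [toy_study("MANY", "", slices=[img.copy() for _ in range(8)])]
        vocab, idx = build_initial_index(corpus, small_cfg)
        page = image_search(idx, vocab, img, config=small_cfg)
        assert page.study_ids() == ["MANY"]
        assert len(page.studies[0].shown_images) == 5
        # ties broken toward lower image ids
        assert [img_id for img_id, _ in page.studies[0].shown_images] == [0, 1, 2, 3, 4]

    def test_min_shared_above_query_bag_empties_page(self, indexed20, small_cfg):
        studies, _t, vocab, idx = indexed20
        query = studies[0].slices[0]
        bag = cs.quantize(
            cs.extract_descriptors(query, config=small_cfg.descriptor), vocab
        )
        page = image_search(
            idx, vocab, query, min_shared=len(bag.counts) + 1, config=small_cfg
        )
        assert len(page) == 0

    def test_featureless_query_rejected(self, indexed20, small_cfg):
        _s, _t, vocab, idx = indexed20
        with pytest.raises(ValueError, match="features"):
            image_search(idx, vocab, np.full((64, 64), 40.0), config=small_cfg)


class TestCombinedSearch:
    def test_both_block_precedes_single_modality(self, small_cfg):
        lesion = cs.generate_study(
            cs.PhantomSpec(seed=21, lesion_class="haemorrhage", image_size=64,
                           n_slices=1)
        ).slices[0]
        blank_like = cs.generate_study(
            cs.PhantomSpec(seed=22, lesion_class="normal", image_size=64, n_slices=1)
        ).slices[0]
        corpus = [
            # A matches both modalities weakly in text
            toy_study("A", "haemorrhage", slices=[lesion]),
            # B matches only text, but much more strongly
            toy_study("B", "haemorrhage haemorrhage haemorrhage acute subdural",
                      slices=[np.full((64, 64), 40.0)]),
        ]
        vocab, idx = build_initial_index(corpus, small_cfg)
        page = combined_search(idx, vocab, "haemorrhage acute subdural",
                               lesion, config=small_cfg)
        assert page.study_ids()[0] == "A"
        assert page.studies[0].match_class == "both"

    def test_full_ordering_matches_oracle(self, indexed20, small_cfg):
        studies, _t, vocab, idx = indexed20
        for qstudy, phrase in [
            (studies[2], "haemorrhage"),
            (studies[7], "infarct basal"),
            (studies[11], "calcification"),
        ]:
            page = combined_search(
                idx, vocab, phrase, qstudy.slices[0], config=small_cfg
            )
            expected = combined_rank(studies, vocab, phrase, qstudy.slices[0],
                                     small_cfg)
            assert [(s.study_id, s.match_class) for s in page.studies] == expected

    def test_empty_corpus_query_terms(self, small_cfg):
        corpus = [toy_study("A", "narrow report")]
        lesion = cs.generate_study(
            cs.PhantomSpec(seed=23, lesion_class="infarct", image_size=64, n_slices=1)
        ).slices[0]
        vocab, idx = build_initial_index(corpus, small_cfg)
        page = combined_search(idx, vocab, "unrelated words", lesion,
                               config=small_cfg)
        assert all(s.match_class == "image_only" for s in page.studies)


class TestFilters:
    META = {
        "A": {"age": 30, "sex": "M", "study_code": "HCT"},
        "B": {"age": 45, "sex": "F", "study_code": "HCT"},
        "C": {"age": 60, "sex": "F", "study_code": "HCTA"},
    }

    def scored(self):
        return [cs.ScoredStudy(study_id=sid) for sid in ("A", "B", "C")]

    def test_no_filters_is_identity(self):
        assert apply_filters(self.scored(), None, self.META) == self.scored()

    def test_age_bounds_inclusive(self):
        kept = apply_filters(
            self.scored(), Filters(age_range=(40, 60)), self.META
        )
        assert [s.study_id for s in kept] == ["B", "C"]

    def test_study_code_exact_match_not_prefix(self):
        kept = apply_filters(
            self.scored(), Filters(study_codes=frozenset({"HCT"})), self.META
        )
        assert [s.study_id for s in kept] == ["A", "B"]

    def test_sex_filter(self):
        kept = apply_filters(self.scored(), Filters(sex="F"), self.META)
        assert [s.study_id for s in kept] == ["B", "C"]

    def test_invalid_age_range_rejected(self):
        with pytest.raises(ValueError, match="age_range"):
            Filters(age_range=(70, 60))

    def test_search_results_respect_filters(self, indexed20, small_cfg):
        studies, _t, vocab, idx = indexed20
        filters = Filters(age_range=(40, 70), sex="F")
        page = text_search(idx, "haemorrhage infarct calcification",
                           filters=filters, config=small_cfg)
        for s in page.studies:
            meta = idx.study_meta(s.study_id)
            assert 40 <= meta["age"] <= 70 and meta["sex"] == "F"
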