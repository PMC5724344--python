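"""Text, image, combined and filtered search over the inverted index.

Scoring is deliberately simple and uniform-weight, mirroring an engine
that treats every term alike:

* text:  score(study) = number of *distinct* query stems present in the
  study's text postings — a ranked AND, so studies matching every query
  stem outrank partial matches; no frequency or rarity weighting enters the
  primary score (matched-stem frequency only breaks ties).
* image: a query bag is extracted from the query slice (optionally an
  ROI); each indexed image scores the number of distinct visual words it
  shares with the query; images below ``min_shared`` drop out; images group
  by study, each study keeps its top-5 images and scores the max.
* combined: studies matching both modalities always precede single-modality
  matches; within the leading block studies rank by the sum of min–max
  normalized per-modality scores (raw stem counts and visual-word counts
  are incommensurable).

Result pages are capped at 100 studies and 5 shown images per study, all
orderings are total and deterministic (scores, then ids), and metadata
filters (age range, sex, study codes) are applied before truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import RunConfig
from .features import VisualVocabulary, extract_descriptors, quantize
from .index import InvertedIndex
from .textproc import stem_tokens, tokenize

__all__ = ["Filters", "ScoredStudy", "ResultPage", "text_search", "image_search",
           "combined_search", "apply_filters"]


@dataclass(frozen=True)
class Filters:
    """Advanced-search constraints; absent fields constrain nothing."""

    age_range: tuple[int, int] | None = None  # inclusive [min, max] years
    sex: str | None = None
    study_codes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.age_range is not None and self.age_range[0] > self.age_range[1]:
            raise ValueError(f"age_range min > max: {self.age_range}")

    def matches(self, meta: dict) -> bool:
        if self.age_range is not None:
            age = meta.get("age")
            if age is None or not self.age_range[0] <= age <= self.age_range[1]:
                return False
        if self.sex is not None and meta.get("sex") != self.sex:
            return False
        if self.study_codes is not None and meta.get("study_code") not in self.study_codes:
            return False
        return True


@dataclass
class ScoredStudy:
    study_id: str
    text_score: int = 0  # matched distinct query stems
    image_score: int = 0  # best shared-visual-word count over kept images
    shown_images: list[tuple[int, int]] = field(default_factory=list)  # (image_id, score)
    match_class: str = "text_only"  # both | text_only | image_only

    def to_dict(self) -> dict[str, Any]:
        return {
            "study_id": self.study_id,
            "text_score": self.text_score,
            "image_score": self.image_score,
            "shown_images": [list(pair) for pair in self.shown_images],
            "match_class": self.match_class,
        }


@dataclass
class ResultPage:
    studies: list[ScoredStudy]
    query: dict[str, Any]
    caps: dict[str, int]

    def __len__(self) -> int:
        return len(self.studies)

    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def to_dict(self) -> dict[str, Any]:
        return {
            "query": self.query,
            "caps": self.caps,
            "studies": [s.to_dict() for s in self.studies],
        }


def apply_filters(
    candidates: list[ScoredStudy],
    filters: Filters | None,
    metadata: dict[str, dict],
) -> list[ScoredStudy]:
    """Keep candidates whose study metadata satisfies every supplied filter."""
    if filters is None:
        return list(candidates)
    return [c for c in candidates if filters.matches(metadata[c.study_id])]


def _query_stems(index: InvertedIndex, phrase: str) -> list[str]:
    tokens = tokenize(phrase)
    if not tokens:
        raise ValueError("empty query: phrase contains no word tokens")
    stemmer = index.manifest.get("stemmer", "porter")
    seen: dict[str, None] = {}
    for stem in stem_tokens(tokens, stemmer):
        seen.setdefault(stem, None)
    return list(seen)


def _score_text(index: InvertedIndex, phrase: str) -> dict[str, tuple[int, int]]:
    """study_id → (distinct matched stems, total matched frequency)."""
    scores: dict[str, list[int]] = {}
    for stem in _query_stems(index, phrase):
        for sid, count in index.text_entries(stem).items():
            entry = scores.setdefault(sid, [0, 0])
            entry[0] += 1
            entry[1] += count
    return {sid: (d, f) for sid, (d, f) in scores.items()}


def _query_bag(
    vocab: VisualVocabulary,
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None,
    config: RunConfig,
) -> dict[int, int]:
    descriptors = extract_descriptors(image, roi=roi, config=config.descriptor)
    if not descriptors:
        raise ValueError("no extractable features in the query image")
    return quantize(descriptors, vocab).counts


def _score_images(
    index: InvertedIndex, query_words: set[int], min_shared: int
) -> dict[str, list[tuple[int, int]]]:
    """study_id → [(image_id, shared-distinct-word count)] above threshold."""
    shared: dict[tuple[str, int], int] = {}
    for word in query_words:
        for (sid, img), _count in index.visual_entries(word).items():
            shared[(sid, img)] = shared.get((sid, img), 0) + 1
    per_study: dict[str, list[tuple[int, int]]] = {}
    for (sid, img), score in shared.items():
        if score >= min_shared:
            per_study.setdefault(sid, []).append((img, score))
    return per_study


def _keep_top_images(
    images: list[tuple[int, int]], cap: int
) -> list[tuple[int, int]]:
    return sorted(images, key=lambda t: (-t[1], t[0]))[:cap]


def text_search(
    index: InvertedIndex,
    phrase: str,
    filters: Filters | None = None,
    config: RunConfig | None = None,
) -> ResultPage:
    """Ranked-AND text search: distinct-stem matches, uniform term weights."""
    config = config or RunConfig()
    raw = _score_text(index, phrase)
    scored = [
        ScoredStudy(study_id=sid, text_score=d, match_class="text_only")
        for sid, (d, _f) in raw.items()
    ]
    scored.sort(
        key=lambda s: (-s.text_score, -raw[s.study_id][1], s.study_id)
    )
    scored = apply_filters(scored, filters, index.manifest["studies"])
    page = scored[: config.max_studies]
    return ResultPage(
        studies=page,
        query={"text": phrase, "filters": _filters_dict(filters)},
        caps={"max_studies": config.max_studies,
              "max_images_per_study": config.max_images_per_study},
    )


def image_search(
    index: InvertedIndex,
    vocab: VisualVocabulary,
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    filters: Filters | None = None,
    min_shared: int | None = None,
    config: RunConfig | None = None,
) -> ResultPage:
    """Visual-word search: studies ranked by their best-matching image."""
    config = config or RunConfig()
    min_shared = config.min_shared if min_shared is None else min_shared
    query_words = set(_query_bag(vocab, image, roi, config))
    per_study = _score_images(index, query_words, min_shared)
    scored = []
    for sid, images in per_study.items():
        kept = _keep_top_images(images, config.max_images_per_study)
        scored.append(
            ScoredStudy(
                study_id=sid,
                image_score=kept[0][1],
                shown_images=kept,
                match_class="image_only",
            )
        )
    scored.sort(key=lambda s: (-s.image_score, s.study_id))
    scored = apply_filters(scored, filters, index.manifest["studies"])
    page = scored[: config.max_studies]
    return ResultPage(
        studies=page,
        query={"image": True, "roi": list(roi) if roi else None,
               "min_shared": min_shared, "filters": _filters_dict(filters)},
        caps={"max_studies": config.max_studies,
              "max_images_per_study": config.max_images_per_study},
    )


def _minmax(scores: dict[str, int]) -> dict[str, float]:
    if not scores:
        return {}
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        return {sid: 1.0 for sid in scores}
    return {sid: (v - lo) / (hi - lo) for sid, v in scores.items()}


def combined_search(
    index: InvertedIndex,
    vocab: VisualVocabulary,
    phrase: str,
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    filters: Filters | None = None,
    config: RunConfig | None = None,
) -> ResultPage:
    """Multimodal search: both-modality matches on top, then single-modality.

    Within the leading block studies rank by the sum of per-modality
    min–max-normalized scores; the trailing block merges text-only and
    image-only matches by their single normalized score (ties: image-only
    first, then study_id).
    """
    config = config or RunConfig()
    text_scores = {sid: d for sid, (d, _f) in _score_text(index, phrase).items()}
    query_words = set(_query_bag(vocab, image, roi, config))
    per_study = _score_images(index, query_words, config.min_shared)
    image_scores = {}
    kept_images = {}
    for sid, images in per_study.items():
        kept = _keep_top_images(images, config.max_images_per_study)
        image_scores[sid] = kept[0][1]
        kept_images[sid] = kept

    norm_text = _minmax(text_scores)
    norm_image = _minmax(image_scores)

    both, text_only, image_only = [], [], []
    for sid in set(text_scores) | set(image_scores):
        s = ScoredStudy(
            study_id=sid,
            text_score=text_scores.get(sid, 0),
            image_score=image_scores.get(sid, 0),
            shown_images=kept_images.get(sid, []),
        )
        if sid in text_scores and sid in image_scores:
            s.match_class = "both"
            both.append(s)
        elif sid in text_scores:
            s.match_class = "text_only"
            text_only.append(s)
        else:
            s.match_class = "image_only"
            image_only.append(s)

    both.sort(
        key=lambda s: (-(norm_text[s.study_id] + norm_image[s.study_id]), s.study_id)
    )

    def single_key(s: ScoredStudy) -> tuple:
        score = (
            norm_image[s.study_id]
            if s.match_class == "image_only"
            else norm_text[s.study_id]
        )
        return (-score, 0 if s.match_class == "image_only" else 1, s.study_id)

    tail = sorted(image_only + text_only, key=single_key)
    scored = apply_filters(both + tail, filters, index.manifest["studies"])
    page = scored[: config.max_studies]
    return ResultPage(
        studies=page,
        query={"text": phrase, "image": True, "roi": list(roi) if roi else None,
               "filters": _filters_dict(filters)},
        caps={"max_studies": config.max_studies,
              "max_images_per_study": config.max_images_per_study},
    )


def _filters_dict(filters: Filters | None) -> dict | None:
    if filters is None:
        return None
    return {
        "age_range": list(filters.age_range) if filters.age_range else None,
        "sex": filters.sex,
        "study_codes": sorted(filters.study_codes) if filters.study_codes else None,
    }
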