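"""Brute-force linear-scan reference implementations of the search rules.

These score every study directly from its raw slices and report, without
the inverted index, and re-state the ranking rules independently of the
search module so that index construction and query execution can be checked
against them on small corpora.
"""

from __future__ import annotations

import numpy as np

from ctsearch.config import RunConfig
from ctsearch.corpus import Study
from ctsearch.features import VisualVocabulary, extract_descriptors, quantize
from ctsearch.textproc import extract_terms, stem_tokens, tokenize


def text_rank(
    studies: list[Study], phrase: str, config: RunConfig
) -> list[tuple[str, int]]:
    """(study_id, score) in result order: distinct-stem matches, uniform weight."""
    query = list(dict.fromkeys(stem_tokens(tokenize(phrase), config.stemmer)))
    rows = []
    for s in studies:
        bag = extract_terms(
            s.report,
            scope=config.text_scope,
            negation=config.negation,
            stemmer=config.stemmer,
            cue_lexicon=config.negation_cues,
        ).counts
        distinct = sum(1 for q in query if q in bag)
        freq = sum(bag.get(q, 0) for q in query)
        if distinct > 0:
            rows.append((s.study_id, distinct, freq))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return [(sid, d) for sid, d, _f in rows[: config.max_studies]]


def _study_image_scores(
    study: Study,
    vocab: VisualVocabulary,
    query_words: set[int],
    config: RunConfig,
    min_shared: int,
) -> list[tuple[int, int]]:
    kept = []
    for image_id, sl in enumerate(study.slices):
        bag = quantize(extract_descriptors(sl, config=config.descriptor), vocab)
        shared = len(query_words & set(bag.counts))
        if shared >= min_shared:
            kept.append((image_id, shared))
    kept.sort(key=lambda t: (-t[1], t[0]))
    return kept[: config.max_images_per_study]


def image_rank(
    studies: list[Study],
    vocab: VisualVocabulary,
    query_image: np.ndarray,
    config: RunConfig,
    roi=None,
    min_shared: int = 1,
) -> list[tuple[str, int, list[tuple[int, int]]]]:
    """(study_id, best score, kept images) in result order."""
    qbag = quantize(
        extract_descriptors(query_image, roi=roi, config=config.descriptor), vocab
    )
    query_words = set(qbag.counts)
    rows = []
    for s in studies:
        kept = _study_image_scores(s, vocab, query_words, config, min_shared)
        if kept:
            rows.append((s.study_id, kept[0][1], kept))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows[: config.max_studies]


def combined_rank(
    studies: list[Study],
    vocab: VisualVocabulary,
    phrase: str,
    query_image: np.ndarray,
    config: RunConfig,
) -> list[tuple[str, str]]:
    """(study_id, match_class) in result order per the partition+normalize rule."""
    text = {sid: score for sid, score in text_rank(studies, phrase, config)}
    image = {
        sid: score for sid, score, _kept in image_rank(
            studies, vocab, query_image, config, min_shared=config.min_shared
        )
    }

    def norm(scores: dict[str, int]) -> dict[str, float]:
        if not scores:
            return {}
        lo, hi = min(scores.values()), max(scores.values())
        return {
            sid: 1.0 if hi == lo else (v - lo) / (hi - lo)
            for sid, v in scores.items()
        }

    nt, ni = norm(text), norm(image)
    both = sorted(
        (sid for sid in text if sid in image),
        key=lambda sid: (-(nt[sid] + ni[sid]), sid),
    )
    singles = [(sid, "image_only") for sid in image if sid not in text]
    singles += [(sid, "text_only") for sid in text if sid not in image]
    singles.sort(
        key=lambda t: (
            -(ni[t[0]] if t[1] == "image_only" else nt[t[0]]),
            0 if t[1] == "image_only" else 1,
            t[0],
        )
    )
    ordered = [(sid, "both") for sid in both] + singles
    return ordered[: config.max_studies]


def nearest_centroid_scan(vector: np.ndarray, centroids: np.ndarray) -> int:
    """Plain-python exhaustive nearest-centroid assignment (ties: lowest index)."""
    best, best_d = 0, None
    for i in range(centroids.shape[0]):
        d = float(np.sum((vector - centroids[i]) ** 2))
        if best_d is None or d < best_d:
            best, best_d = i, d
    return best
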