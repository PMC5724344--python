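"""Unified inverted index over text stems and visual words.

One physical index serves both modalities: terms are namespaced
``t:<stem>`` for report stems and ``v:<id>`` for visual words. A posting
maps a term to entries ``(study_id, image_id, count)``; text entries carry
``image_id = None`` (text belongs to the study), visual entries carry the
concrete slice index.

Indexing happens in two phases, as in a deployed system:

* *initial indexing* — a corpus trains the visual vocabulary (k-means over
  sampled descriptors) and every study's images and report are indexed;
* *background indexing* — newly arriving studies are indexed with the
  frozen vocabulary, never retraining it. Unseen text stems are indexed by
  default (open lexicon); ``strict_text=True`` drops them, preserving a
  literal frozen-text-vocabulary reading.

Persistence is a directory of text files: ``manifest.json``,
``postings.jsonl`` (one term per line, sorted), and the vocabulary files.
Checksums in the manifest guard against truncation and tampering.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import features
from .config import RunConfig
from .corpus import Study
from .features import VisualVocabulary, extract_descriptors, quantize
from .textproc import extract_terms

__all__ = [
    "InvertedIndex",
    "IndexError_",
    "IndexIntegrityError",
    "build_initial_index",
    "background_index",
    "save_index",
    "load_index",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

Entry = tuple[str, int | None]  # (study_id, image_id)


class IndexError_(ValueError):
    """Invalid indexing request (duplicate study, vocabulary mismatch...)."""


class IndexIntegrityError(RuntimeError):
    """Persisted index failed a version or checksum check."""


class InvertedIndex:
    """Term → {(study_id, image_id): count}, plus the build manifest."""

    def __init__(self, manifest: dict | None = None) -> None:
        self.postings: dict[str, dict[Entry, int]] = {}
        self.manifest: dict = manifest or {
            "format_version": FORMAT_VERSION,
            "vocab_checksum": None,
            "stemmer": "porter",
            "scope": "report_only",
            "negation": True,
            "studies": {},
            "phases": [],
        }
        self.vocab: VisualVocabulary | None = None

    # -- queries used by the search layer -----------------------------------
    def study_ids(self) -> set[str]:
        return set(self.manifest["studies"])

    def study_meta(self, study_id: str) -> dict:
        return self.manifest["studies"][study_id]

    def text_entries(self, stem: str) -> dict[str, int]:
        """study_id → count for one text stem."""
        posting = self.postings.get(f"t:{stem}", {})
        return {sid: c for (sid, _img), c in posting.items()}

    def visual_entries(self, word: int) -> dict[tuple[str, int], int]:
        """(study_id, image_id) → count for one visual word."""
        posting = self.postings.get(f"v:{word}", {})
        return {(sid, img): c for (sid, img), c in posting.items()}

    # -- construction --------------------------------------------------------
    def _add_bag(self, term_prefix: str, study_id: str, image_id: int | None,
                 counts: dict) -> None:
        for key, count in counts.items():
            term = f"{term_prefix}:{key}"
            posting = self.postings.setdefault(term, {})
            entry = (study_id, image_id)
            if entry in posting:
                raise IndexError_(f"duplicate entry {entry} for term {term}")
            posting[entry] = int(count)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InvertedIndex):
            return NotImplemented
        return self.postings == other.postings and _strip_times(
            self.manifest
        ) == _strip_times(other.manifest)


def _strip_times(manifest: dict) -> dict:
    m = copy.deepcopy(manifest)
    m["phases"] = [
        {k: v for k, v in phase.items() if k != "timestamp"}
        for phase in m.get("phases", [])
    ]
    return m


def _index_study(index: InvertedIndex, study: Study, vocab: VisualVocabulary,
                 config: RunConfig) -> None:
    sid = study.study_id
    for image_id, sl in enumerate(study.slices):
        bag = quantize(
            extract_descriptors(sl, config=config.descriptor), vocab, image_id
        )
        index._add_bag("v", sid, image_id, bag.counts)
    terms = extract_terms(
        study.report,
        scope=config.text_scope,
        negation=config.negation,
        stemmer=config.stemmer,
        cue_lexicon=config.negation_cues,
    )
    index._add_bag("t", sid, None, terms.counts)
    index.manifest["studies"][sid] = {
        "age": study.patient_age,
        "sex": study.patient_sex,
        "study_code": study.study_code,
        "n_images": len(study.slices),
        "status": "ok",
    }


def _sample_descriptors(
    corpus: list[Study], config: RunConfig
) -> list[features.Descriptor]:
    descriptors: list[features.Descriptor] = []
    for study in corpus:
        try:
            for sl in study.slices:
                descriptors.extend(extract_descriptors(sl, config=config.descriptor))
        except Exception:  # noqa: BLE001 — bad study recorded at indexing time
            logger.exception(
                "cannot sample descriptors from study %s", study.study_id
            )
    if len(descriptors) > config.vocab_max_samples:
        rng = np.random.default_rng(config.vocab_seed)
        keep = rng.choice(len(descriptors), config.vocab_max_samples, replace=False)
        descriptors = [descriptors[i] for i in sorted(keep)]
    return descriptors


def build_initial_index(
    corpus: list[Study],
    config: RunConfig | None = None,
    vocab: VisualVocabulary | None = None,
) -> tuple[VisualVocabulary, InvertedIndex]:
    """Phase one: train the visual vocabulary (unless given) and index the corpus.

    Studies that fail to index are skipped, logged, and recorded in the
    manifest with status "failed" — a batch never aborts on one bad study.
    """
    if not corpus:
        raise IndexError_("corpus must be non-empty")
    config = config or RunConfig()
    if vocab is None:
        sample = _sample_descriptors(corpus, config)
        if sample:
            # a small corpus may yield fewer descriptors than vocab_k
            vocab = features.build_vocabulary(
                sample, k=min(config.vocab_k, len(sample)),
                seed=config.vocab_seed, config=config.descriptor,
            )
        else:
            # featureless corpus (e.g. blank phantoms): empty visual side
            vocab = VisualVocabulary(
                centroids=np.zeros((1, config.descriptor.length)),
                training_seed=config.vocab_seed,
                descriptor_config=config.descriptor,
            )

    index = InvertedIndex()
    index.manifest.update(
        {
            "vocab_checksum": vocab.checksum,
            "stemmer": config.stemmer,
            "scope": config.text_scope,
            "negation": config.negation,
            "negation_cues": sorted(config.negation_cues),
            "descriptor_config": asdict(config.descriptor),
        }
    )
    index.vocab = vocab
    failed = []
    for study in corpus:
        if study.study_id in index.manifest["studies"]:
            raise IndexError_(f"duplicate study_id {study.study_id!r} in corpus")
        try:
            _index_study(index, study, vocab, config)
        except IndexError_:
            raise
        except Exception:  # noqa: BLE001 — resilience contract
            logger.exception("failed to index study %s; skipping", study.study_id)
            index.manifest["studies"][study.study_id] = {"status": "failed"}
            failed.append(study.study_id)
    index.manifest["phases"].append(
        {
            "phase": "initial",
            "n_studies": len(corpus),
            "failed": failed,
            "timestamp": time.time(),
        }
    )
    return vocab, index


def background_index(
    index: InvertedIndex,
    vocab: VisualVocabulary,
    new_studies: list[Study],
    config: RunConfig | None = None,
    strict_text: bool = False,
) -> InvertedIndex:
    """Phase two: index new studies against the frozen vocabulary, in place.

    With ``strict_text=True`` stems unseen during the initial phase are
    dropped rather than added (closed text lexicon).
    """
    config = config or RunConfig()
    if vocab.checksum != index.manifest["vocab_checksum"]:
        raise IndexError_(
            "vocabulary checksum mismatch: refusing to index with a "
            "different vocabulary than the one in the manifest"
        )
    dupes = [s.study_id for s in new_studies if s.study_id in index.manifest["studies"]]
    if dupes:
        raise IndexError_(f"studies already indexed: {dupes}")
    known_stems = None
    if strict_text:
        known_stems = {t for t in index.postings if t.startswith("t:")}
    failed = []
    for study in new_studies:
        try:
            _index_study(index, study, vocab, config)
        except Exception:  # noqa: BLE001
            logger.exception("failed to index study %s; skipping", study.study_id)
            index.manifest["studies"][study.study_id] = {"status": "failed"}
            failed.append(study.study_id)
    if known_stems is not None:
        for term in [
            t for t in index.postings if t.startswith("t:") and t not in known_stems
        ]:
            del index.postings[term]
    index.manifest["phases"].append(
        {
            "phase": "background",
            "n_studies": len(new_studies),
            "failed": failed,
            "timestamp": time.time(),
        }
    )
    return index


# ---------------------------------------------------------------------------
# Persistence

def serialize_postings(index: InvertedIndex) -> str:
    """Deterministic JSONL text: terms sorted, entries sorted by (study, image)."""
    lines = []
    for term in sorted(index.postings):
        entries = sorted(
            index.postings[term].items(),
            key=lambda kv: (kv[0][0], -1 if kv[0][1] is None else kv[0][1]),
        )
        lines.append(
            json.dumps(
                {
                    "term": term,
                    "entries": [[sid, img, count] for (sid, img), count in entries],
                },
                sort_keys=True,
                separators=(",", ":"),
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def save_index(index: InvertedIndex, directory: str | Path) -> None:
    """Write manifest.json + postings.jsonl (+ vocabulary files if attached)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    postings_text = serialize_postings(index)
    (directory / "postings.jsonl").write_text(postings_text)
    manifest = copy.deepcopy(index.manifest)
    manifest["format_version"] = FORMAT_VERSION
    manifest["postings_checksum"] = hashlib.sha256(
        postings_text.encode()
    ).hexdigest()
    if index.vocab is not None:
        features.save_vocabulary(index.vocab, directory)
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )


def load_index(directory: str | Path) -> InvertedIndex:
    """Load a persisted index, verifying version and checksums."""
    directory = Path(directory)
    try:
        manifest = json.loads((directory / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise IndexIntegrityError(f"cannot read index manifest: {exc}") from exc
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise IndexIntegrityError(
            f"index format version {version!r}; expected {FORMAT_VERSION}"
        )
    postings_text = (directory / "postings.jsonl").read_text()
    digest = hashlib.sha256(postings_text.encode()).hexdigest()
    if digest != manifest.get("postings_checksum"):
        raise IndexIntegrityError(
            "postings checksum mismatch: index file truncated or modified"
        )
    index = InvertedIndex(manifest={
        k: v for k, v in manifest.items() if k != "postings_checksum"
    })
    for line in postings_text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        index.postings[rec["term"]] = {
            (sid, img): count for sid, img, count in rec["entries"]
        }
    if (directory / "vocab.json").exists():
        index.vocab = features.load_vocabulary(directory)
        if index.vocab.checksum != manifest.get("vocab_checksum"):
            raise IndexIntegrityError("vocabulary checksum mismatch with manifest")
    return index
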