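"""Report-text processing: tokenization, stemming, negation filtering, term bags.

Radiological studies carry two text fields: the *anamnesis* (the clinical
question accompanying the study request, e.g. "Suspected haemorrhage?") and
the *report text* (the radiologist's findings and conclusion). Indexing the
anamnesis causes false positives — a study whose request merely asks about a
finding matches a query for that finding — so the default field scope is
``report_only``; ``report_and_anamnesis`` reproduces the broader behaviour.

Finding terms inside negative expressions ("No acute haemorrhage.") are
removed by a cue-based filter before indexing: a negation cue suppresses
every following token up to the end of its sentence. The cue lexicon is a
plain word set, loadable from a one-cue-per-line text file, and deliberately
extensible — simple cue rules are known to be imperfect on real reports.

All surviving stems carry equal weight: term bags hold raw occurrence
counts and no tf-idf or rarity weighting exists anywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .stemming import Stemmer, get_stemmer

__all__ = [
    "ReportDocument",
    "TermBag",
    "DEFAULT_NEGATION_CUES",
    "SCOPES",
    "tokenize",
    "tokenize_sentences",
    "stem_tokens",
    "filter_negated",
    "extract_terms",
    "load_cue_lexicon",
]

#: Default negation cue words. "ei" is the placeholder slot for localized
#: (e.g. Finnish) cues; the lexicon is meant to be extended per deployment.
DEFAULT_NEGATION_CUES = frozenset({"no", "not", "without", "ei"})

SCOPES = ("report_only", "report_and_anamnesis")

_SENTENCE_SPLIT = re.compile(r"[.!?]+")
_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class ReportDocument:
    """The textual half of one radiological study."""

    study_id: str
    anamnesis: str = ""
    report_text: str = ""

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")


@dataclass
class TermBag:
    """Stem → occurrence count for one document under a given field scope."""

    counts: dict[str, int] = field(default_factory=dict)
    scope: str = "report_only"

    def __post_init__(self) -> None:
        for stem, count in self.counts.items():
            if not stem or stem != stem.lower():
                raise ValueError(f"stems must be lowercase and non-empty: {stem!r}")
            if count < 1:
                raise ValueError(f"counts must be >= 1: {stem!r} -> {count}")


def tokenize_sentences(text: str) -> list[list[str]]:
    """Split text into sentences (on ``. ! ?``) of lowercase word tokens.

    Tokens are maximal alphanumeric runs; punctuation splits tokens. Sentence
    structure is preserved because negation scoping stops at sentence
    boundaries.
    """
    sentences = []
    for raw in _SENTENCE_SPLIT.split(text.lower()):
        tokens = _TOKEN.findall(raw)
        if tokens:
            sentences.append(tokens)
    return sentences


def tokenize(text: str) -> list[str]:
    """Flat token sequence of `text` (see :func:`tokenize_sentences`)."""
    return [tok for sent in tokenize_sentences(text) for tok in sent]


def stem_tokens(tokens: Sequence[str], stemmer: Stemmer | str = "porter") -> list[str]:
    """Apply the stemmer to each token; non-alphabetic tokens pass through."""
    if isinstance(stemmer, str):
        stemmer = get_stemmer(stemmer)
    return [stemmer.stem(tok) for tok in tokens]


def filter_negated(
    sentences: Iterable[Sequence[str]],
    cue_lexicon: Iterable[str] = DEFAULT_NEGATION_CUES,
) -> list[str]:
    """Drop tokens in the scope of a negation cue.

    Within each sentence, the first cue token and everything after it up to
    the sentence end are removed; negation never crosses a sentence
    boundary. Returns the surviving tokens in order.
    """
    cues = frozenset(cue_lexicon)
    if not cues:
        raise ValueError("cue lexicon must be non-empty")
    survivors: list[str] = []
    for sentence in sentences:
        for tok in sentence:
            if tok in cues:
                break
            survivors.append(tok)
    return survivors


def extract_terms(
    doc: ReportDocument,
    scope: str = "report_only",
    negation: bool = True,
    stemmer: Stemmer | str = "porter",
    cue_lexicon: Iterable[str] = DEFAULT_NEGATION_CUES,
) -> TermBag:
    """Tokenize → negation-filter → stem → count the indexable fields of `doc`."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    texts = [doc.report_text]
    if scope == "report_and_anamnesis":
        texts.append(doc.anamnesis)
    counts: dict[str, int] = {}
    for text in texts:
        sentences = tokenize_sentences(text)
        if negation:
            tokens = filter_negated(sentences, cue_lexicon)
        else:
            tokens = [tok for sent in sentences for tok in sent]
        for stem in stem_tokens(tokens, stemmer):
            if stem:
                counts[stem] = counts.get(stem, 0) + 1
    return TermBag(counts=counts, scope=scope)


def load_cue_lexicon(path: str | Path) -> frozenset[str]:
    """Read a negation cue lexicon: one cue per line, blanks and # comments ignored."""
    cues = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            cues.add(line)
    if not cues:
        raise ValueError(f"cue lexicon file {path} contains no cues")
    return frozenset(cues)
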