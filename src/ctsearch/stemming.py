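"""Pluggable stemmers for report-text indexing.

The retrieval engine indexes report words in truncated (stemmed) form so
that inflected variants of a finding term match each other at query time.
The production system this models handled Finnish; here the default stemmer
is an English Porter suffix-stripper, implemented from the published
algorithm, and the stemmer is pluggable so other languages (or an identity
stemmer for exact-term matching) can be swapped in.
"""

from __future__ import annotations

from typing import Callable, Protocol

__all__ = ["Stemmer", "PorterStemmer", "IdentityStemmer", "get_stemmer", "STEMMERS"]


class Stemmer(Protocol):
    id: str

    def stem(self, token: str) -> str: ...


class IdentityStemmer:
    """Returns tokens unchanged; useful for exact-term tests and debugging."""

    id = "identity"

    def stem(self, token: str) -> str:
        return token


_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel→consonant transitions, the Porter 'm' of [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """Consonant-vowel-consonant ending where the final consonant is not w, x or y."""
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


class PorterStemmer:
    """Classic Porter (1980) suffix-stripping stemmer for English.

    Applied only to alphabetic tokens longer than two characters; numeric
    and very short tokens pass through unchanged, so e.g. "3" stays "3".
    """

    id = "porter"

    def stem(self, token: str) -> str:
        if len(token) <= 2 or not token.isalpha():
            return token
        word = self._step1a(token)
        word = self._step1b(word)
        word = self._step1c(word)
        word = self._step2(word)
        word = self._step3(word)
        word = self._step4(word)
        word = self._step5a(word)
        word = self._step5b(word)
        return word

    @staticmethod
    def _step1a(w: str) -> str:
        if w.endswith("sses"):
            return w[:-2]
        if w.endswith("ies"):
            return w[:-2]
        if w.endswith("ss"):
            return w
        if w.endswith("s"):
            return w[:-1]
        return w

    @staticmethod
    def _step1b(w: str) -> str:
        if w.endswith("eed"):
            if _measure(w[:-3]) > 0:
                return w[:-1]
            return w
        stripped = None
        if w.endswith("ed") and _contains_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _contains_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is None:
            return w
        if stripped.endswith(("at", "bl", "iz")):
            return stripped + "e"
        if _ends_double_consonant(stripped) and stripped[-1] not in "lsz":
            return stripped[:-1]
        if _measure(stripped) == 1 and _ends_cvc(stripped):
            return stripped + "e"
        return stripped

    @staticmethod
    def _step1c(w: str) -> str:
        if w.endswith("y") and _contains_vowel(w[:-1]):
            return w[:-1] + "i"
        return w

    @staticmethod
    def _step2(w: str) -> str:
        for suffix, repl in _STEP2:
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if _measure(stem) > 0:
                    return stem + repl
                return w
        return w

    @staticmethod
    def _step3(w: str) -> str:
        for suffix, repl in _STEP3:
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if _measure(stem) > 0:
                    return stem + repl
                return w
        return w

    @staticmethod
    def _step4(w: str) -> str:
        for suffix in _STEP4:
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if _measure(stem) > 1:
                    if suffix == "ion" and stem and stem[-1] not in "st":
                        return w
                    return stem
                return w
        return w

    @staticmethod
    def _step5a(w: str) -> str:
        if w.endswith("e"):
            stem = w[:-1]
            m = _measure(stem)
            if m > 1 or (m == 1 and not _ends_cvc(stem)):
                return stem
        return w

    @staticmethod
    def _step5b(w: str) -> str:
        if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
            return w[:-1]
        return w


STEMMERS: dict[str, Callable[[], Stemmer]] = {
    "porter": PorterStemmer,
    "identity": IdentityStemmer,
}


def get_stemmer(stemmer_id: str) -> Stemmer:
    """Look up a stemmer by its registry id ("porter" or "identity")."""
    try:
        return STEMMERS[stemmer_id]()
    except KeyError:
        raise ValueError(
            f"unknown stemmer {stemmer_id!r}; available: {sorted(STEMMERS)}"
        ) from None
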