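"""Text metrics: syllable counting and reference-vs-ASR word overlap.

The syllable counter is the vowel-cluster heuristic used for articulation
rate: count maximal vowel clusters, subtract one for a silent final 'e',
add one back for a consonant+'le' ending, and never return less than one.
``match_fraction`` is the hallucination screen used by the QA cascade: the
fraction of reference words (as a multiset) that the ASR hypothesis
reproduces, case- and punctuation-insensitive.
"""

from __future__ import annotations

import re
from collections import Counter

__all__ = [
    "normalize_token",
    "normalize_text",
    "count_syllables",
    "count_syllables_text",
    "match_fraction",
]

# 'y' counts as a vowel so words like "rhythm" and "my" get a cluster
# before the at-least-one floor applies.
_VOWELS = frozenset("aeiouy")

_STRIP_RE = re.compile(r"[^a-z']+")
_APOSTROPHE_EDGE_RE = re.compile(r"^'+|'+$")


def normalize_token(word: str) -> str:
    """Lower-case a word and strip everything but letters and internal apostrophes."""
    w = _STRIP_RE.sub("", word.lower())
    return _APOSTROPHE_EDGE_RE.sub("", w)


def normalize_text(text: str) -> list[str]:
    """Split free text into normalized tokens, dropping tokens that normalize to nothing."""
    return [t for t in (normalize_token(w) for w in text.split()) if t]


def count_syllables(word: str) -> int:
    """Count syllables in one word by its vowel clusters.

    A syllable is scored for every vowel that follows a non-vowel (a maximal
    vowel cluster). A final silent 'e' removes one count; a final 'le'
    preceded by a consonant restores it ("little" -> 2). At least one
    syllable is always counted ("rhythm" -> 1).

    Parameters
    ----------
    word : str
        A normalized token (lower-case letters, optional internal apostrophe).

    Returns
    -------
    int
        Syllable count, always >= 1.
    """
    w = normalize_token(word)
    if not w or not any(c.isalpha() for c in w):
        raise ValueError(f"not a countable word: {word!r}")
    letters = w.replace("'", "")
    count = 0
    prev_vowel = False
    for c in letters:
        is_vowel = c in _VOWELS
        if is_vowel and not prev_vowel:
            count += 1
        prev_vowel = is_vowel
    if letters.endswith("e"):
        count -= 1
    if letters.endswith("le") and len(letters) >= 3 and letters[-3] not in _VOWELS:
        count += 1
    return max(count, 1)


def count_syllables_text(tokens: list[str]) -> int:
    """Total syllables over a token list (empty list counts zero)."""
    return sum(count_syllables(t) for t in tokens)


def match_fraction(reference: str, hypothesis: str) -> float:
    """Fraction of reference words the hypothesis reproduces.

    Word-multiset overlap relative to the reference: order-insensitive, so a
    re-ordered but faithful transcript scores 1.0, while hallucinated content
    that shares no vocabulary with the presented sentence scores 0.0. The QA
    cascade keeps recordings with ``match_fraction >= 0.20`` (inclusive).
    """
    ref = normalize_text(reference)
    if not ref:
        raise ValueError("reference text is empty")
    hyp = Counter(normalize_text(hypothesis))
    overlap = sum(min(n, hyp[w]) for w, n in Counter(ref).items())
    return overlap / len(ref)
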