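"""Deterministic text repair and feature extraction for free-text job titles.

Survey answers to "What is your job title?" arrive in mixed case, with
inserted symbols ("Bartender/waiter"), typographical errors ("Constuction")
and modifier-laden phrases ("certified accontant").  This module provides
the repair primitives the coding pipeline composes: normalization, symbol
splitting, tokenization, stop-word removal, suffix-stripping stemming,
noun extraction and vocabulary-based spelling correction.

All operations are pure and deterministic for a fixed :class:`TextConfig`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from ._distance import damerau_levenshtein
from ._porter import porter_stem

_WS_RE = re.compile(r"\s+")
# anything that is not a word character or whitespace acts as a separator
_PUNCT_RE = re.compile(r"[^\w\s]|_")
_SPLIT_RE = re.compile(r"[/\-]|[^\w\s]|_")


def _load_default_stop_words() -> frozenset[str]:
    text = resources.files("occucoder.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(line.strip() for line in text.splitlines()
                     if line.strip() and not line.startswith("#"))


@dataclass(frozen=True)
class TextConfig:
    """Configuration for the text-repair primitives.

    Attributes
    ----------
    stop_words:
        Tokens removed by :func:`remove_stop_words`; a small fixed English
        list is shipped with the package and used by default.
    stemmer:
        Name of the stemmer; only ``"porter"`` is built in.
    tagger:
        Noun tagger name.  ``"heuristic"`` (default) flags every token that
        is neither a stop word nor a known adjective-like modifier, falling
        back to the last token when nothing survives.
    spell_max_distance:
        Maximum Damerau-Levenshtein distance for spelling correction.
    """

    stop_words: frozenset[str] = field(default_factory=_load_default_stop_words)
    stemmer: str = "porter"
    tagger: str = "heuristic"
    spell_max_distance: int = 2


DEFAULT_CONFIG = TextConfig()


def normalize(text: str) -> str:
    """Casefold, trim, and collapse internal whitespace runs to one space."""
    return _WS_RE.sub(" ", text.casefold().strip())


def tokenize(text: str) -> list[str]:
    """Split normalized text into tokens; punctuation acts as whitespace."""
    return _PUNCT_RE.sub(" ", normalize(text)).split()


def split_on_symbols(text: str) -> list[str]:
    """Split a title on inserted symbols ("/", "-", punctuation).

    Returns the normalized non-empty parts in their original order; a title
    without symbols comes back as a single-element list.

    >>> split_on_symbols("Bartender/waiter")
    ['bartender', 'waiter']
    """
    parts = (normalize(p) for p in _SPLIT_RE.split(text))
    return [p for p in parts if p] or ([normalize(text)] if normalize(text) else [])


def remove_stop_words(tokens: Sequence[str],
                      config: TextConfig = DEFAULT_CONFIG) -> list[str]:
    """Drop stop-list tokens, preserving the order of the survivors."""
    return [t for t in tokens if t not in config.stop_words]


def stem_tokens(tokens: Sequence[str],
                config: TextConfig = DEFAULT_CONFIG) -> list[str]:
    """Replace each token by its suffix-stripped stem."""
    if config.stemmer != "porter":
        raise ValueError(f"unknown stemmer: {config.stemmer!r}")
    return [porter_stem(t) for t in tokens]


def extract_nouns(tokens: Sequence[str],
                  config: TextConfig = DEFAULT_CONFIG) -> list[str]:
    """Return the sub-sequence of tokens judged to be nouns.

    The heuristic tagger treats a token as a noun unless it is a stop word
    or carries a typical adjectival suffix; when no token qualifies, the
    last token is returned so the result is never empty for non-empty
    input (job titles end in their head noun far more often than not:
    "agricultural producer", "certified accountant").
    """
    if not tokens:
        return []
    if config.tagger != "heuristic":
        raise ValueError(f"unknown tagger: {config.tagger!r}")
    nouns = [t for t in tokens
             if t not in config.stop_words and not _looks_adjectival(t)]
    return nouns if nouns else [tokens[-1]]


_ADJ_SUFFIXES = ("al", "ic", "ive", "ous", "ful", "less", "ing", "ed")


def _looks_adjectival(token: str) -> bool:
    # modifier heuristics: derivational adjective endings on long tokens
    return len(token) > 5 and token.endswith(_ADJ_SUFFIXES)


def spell_correct(token: str, vocabulary: Mapping[str, int],
                  max_distance: int = 2) -> str:
    """Correct ``token`` against a frequency-weighted vocabulary.

    A token already in the vocabulary is returned unchanged.  Otherwise the
    vocabulary entry within ``max_distance`` Damerau-Levenshtein edits with
    the highest corpus frequency is returned (ties broken by lexicographic
    order); if no entry is close enough the token is returned as is.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    if token in vocabulary:
        return token
    best: str | None = None
    best_freq = -1
    for word, freq in vocabulary.items():
        if damerau_levenshtein(token, word, max_distance=max_distance) <= max_distance:
            if freq > best_freq or (freq == best_freq and (best is None or word < best)):
                best, best_freq = word, freq
    return best if best is not None else token


def correct_tokens(tokens: Iterable[str], vocabulary: Mapping[str, int],
                   max_distance: int = 2) -> list[tuple[str, str]]:
    """Spell-correct each token; returns (original, corrected) pairs."""
    return [(t, spell_correct(t, vocabulary, max_distance)) for t in tokens]


@dataclass(frozen=True)
class TokenizedTitle:
    """A title with its derived token views."""

    raw: str
    normalized: str
    tokens: tuple[str, ...]
    nouns: tuple[str, ...]

    @classmethod
    def from_text(cls, text: str,
                  config: TextConfig = DEFAULT_CONFIG) -> "TokenizedTitle":
        tokens = tuple(tokenize(text))
        return cls(raw=text, normalized=normalize(text), tokens=tokens,
                   nouns=tuple(extract_nouns(tokens, config)))
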