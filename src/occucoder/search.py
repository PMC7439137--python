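"""The seven-strategy search cascade over a NOC classification.

A query (a job title or an industry description) is matched against scoped
classification text -- occupational titles, group names at levels 1-3, and
unit-group descriptions -- by a sequence of progressively weaker
strategies, strongest first:

``EXACT``
    the normalized query equals the scoped text;
``MINOR_EXACT``
    exact after spell-correcting each query token against the
    classification's own vocabulary;
``LIKE``
    the normalized query appears as a contiguous substring;
``NEAR_SAME_ORDER``
    every query token occurs, in the same relative order;
``NEAR_DIFF_ORDER``
    every query token occurs, in any order;
``ANY``
    at least one query token occurs;
``WEAK``
    at least one query *noun* occurs (and the scope widens to the
    unit-group descriptions).

The strategy semantics are cumulative by construction -- each tier accepts
everything its stronger neighbour accepts -- so the hit sets are nested:
EXACT ⊆ LIKE ⊆ NEAR_SAME_ORDER ⊆ NEAR_DIFF_ORDER ⊆ ANY ⊇ WEAK.  A match
against a level 1-3 group *name* yields one hit per unit group beneath it,
which is how a bare "TEACHER" can reach every unit group of the
secondary-and-elementary-teachers minor group.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .noc import NocDatabase, NocError
from .textprep import (TextConfig, DEFAULT_CONFIG, extract_nouns, normalize,
                       spell_correct, stem_tokens, tokenize)


class SearchStrategy(enum.IntEnum):
    """The cascade order; lower value = stronger strategy."""

    EXACT = 1
    MINOR_EXACT = 2
    LIKE = 3
    NEAR_SAME_ORDER = 4
    NEAR_DIFF_ORDER = 5
    ANY = 6
    WEAK = 7


STRATEGY_ORDER: tuple[SearchStrategy, ...] = tuple(SearchStrategy)


class ScopeField(enum.Enum):
    TITLES = "titles"
    GROUP_NAMES = "group_names"
    LEAD_STATEMENT = "lead_statement"
    MAIN_DUTIES = "main_duties"
    EMPLOYMENT_REQUIREMENTS = "employment_requirements"


SearchScope = frozenset  # of ScopeField

SCOPE_TITLES: frozenset[ScopeField] = frozenset({ScopeField.TITLES})
SCOPE_TITLES_NAMES: frozenset[ScopeField] = frozenset(
    {ScopeField.TITLES, ScopeField.GROUP_NAMES})
SCOPE_FULL: frozenset[ScopeField] = frozenset(ScopeField)

SCOPE_PRESETS = {"titles": SCOPE_TITLES, "titles+names": SCOPE_TITLES_NAMES,
                 "full": SCOPE_FULL}


@dataclass(frozen=True)
class SearchHit:
    """A candidate unit-group code with its match provenance."""

    code: str
    matched_field: ScopeField
    matched_text: str
    strategy: SearchStrategy


def _scoped_texts(db: NocDatabase,
                  scope: frozenset[ScopeField]) -> Iterable[tuple[str, tuple[str, ...], ScopeField]]:
    """Yield (text, unit codes it stands for, field) for the scope."""
    if ScopeField.TITLES in scope:
        for unit in db.unit_groups.values():
            for title in unit.all_titles:
                yield title, (unit.code,), ScopeField.TITLES
    if ScopeField.GROUP_NAMES in scope:
        for level in (db.broad_categories, db.major_groups, db.minor_groups):
            for group in level.values():
                yield group.name, tuple(db.descendants(group.code)), ScopeField.GROUP_NAMES
    field_map = ((ScopeField.LEAD_STATEMENT, "lead_statement"),
                 (ScopeField.MAIN_DUTIES, "main_duties"),
                 (ScopeField.EMPLOYMENT_REQUIREMENTS, "employment_requirements"))
    for scope_field, attr in field_map:
        if scope_field in scope:
            for unit in db.unit_groups.values():
                text = getattr(unit, attr)
                if text:
                    yield text, (unit.code,), scope_field


def _is_subsequence(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    it = iter(haystack)
    return all(tok in it for tok in needle)


def _matches(strategy: SearchStrategy, query_norm: str,
             query_tokens: Sequence[str], query_nouns: Sequence[str],
             text_norm: str, text_tokens: Sequence[str]) -> bool:
    if strategy is SearchStrategy.EXACT:
        return query_norm == text_norm
    if strategy is SearchStrategy.MINOR_EXACT:
        # receives an already-corrected query; compares token sequences so
        # punctuation inside titles cannot break equality
        return query_norm == text_norm or list(query_tokens) == list(text_tokens)
    substring = query_norm in text_norm
    if strategy is SearchStrategy.LIKE:
        return substring
    token_set = set(text_tokens)
    if strategy is SearchStrategy.NEAR_SAME_ORDER:
        return substring or _is_subsequence(query_tokens, text_tokens)
    if strategy is SearchStrategy.NEAR_DIFF_ORDER:
        return substring or all(t in token_set for t in query_tokens)
    if strategy is SearchStrategy.ANY:
        return substring or any(t in token_set for t in query_tokens)
    if strategy is SearchStrategy.WEAK:
        return any(t in token_set for t in query_nouns)
    raise NocError(f"unknown strategy: {strategy!r}")


def run_strategy(strategy: SearchStrategy, query: str, db: NocDatabase,
                 scope: frozenset[ScopeField] = SCOPE_TITLES_NAMES, *,
                 stem: bool = False,
                 config: TextConfig = DEFAULT_CONFIG) -> set[SearchHit]:
    """Run one strategy; returns the set of hits (possibly empty).

    With ``stem=True`` token comparison (and the normalized forms used for
    equality/substring tests) is performed on suffix-stripped stems,
    applied symmetrically to query and classification text.
    """
    query_norm = normalize(query)
    if not query_norm:
        raise NocError("empty query")
    query_tokens: list[str] = tokenize(query)
    if strategy is SearchStrategy.MINOR_EXACT:
        query_tokens = [spell_correct(t, db.vocabulary, config.spell_max_distance)
                        for t in query_tokens]
        query_norm = " ".join(query_tokens)
    if stem:
        query_tokens = stem_tokens(query_tokens, config)
        query_norm = " ".join(query_tokens)
    query_nouns = extract_nouns(query_tokens, config)

    hits: set[SearchHit] = set()
    for text, codes, scope_field in _scoped_texts(db, scope):
        text_tokens = tokenize(text)
        if stem:
            text_tokens = stem_tokens(text_tokens, config)
            text_norm = " ".join(text_tokens)
        else:
            text_norm = normalize(text)
        if _matches(strategy, query_norm, query_tokens, query_nouns,
                    text_norm, text_tokens):
            for code in codes:
                hits.add(SearchHit(code=code, matched_field=scope_field,
                                   matched_text=text, strategy=strategy))
    return hits


def multi_search(query: str, db: NocDatabase,
                 scope: frozenset[ScopeField] = SCOPE_TITLES_NAMES, *,
                 stem: bool = False,
                 strategies: Sequence[SearchStrategy] = STRATEGY_ORDER,
                 config: TextConfig = DEFAULT_CONFIG,
                 attempted: list[SearchStrategy] | None = None,
                 ) -> tuple[set[SearchHit], SearchStrategy | None]:
    """Run the cascade strongest-to-weakest; stop at the first non-empty.

    ``attempted``, when given, records every strategy actually executed
    (the short-circuit contract is thereby observable).  The WEAK strategy
    widens the scope to include unit-group descriptions, which is where
    the weakest noun matching is allowed to look.
    """
    for strategy in strategies:
        if attempted is not None:
            attempted.append(strategy)
        strat_scope = scope | {ScopeField.LEAD_STATEMENT, ScopeField.MAIN_DUTIES,
                               ScopeField.EMPLOYMENT_REQUIREMENTS} \
            if strategy is SearchStrategy.WEAK else scope
        hits = run_strategy(strategy, query, db, strat_scope,
                            stem=stem, config=config)
        if hits:
            return hits, strategy
    return set(), None


# ---------------------------------------------------------------------------
# independent oracle (tests only)
# ---------------------------------------------------------------------------

def brute_force_match(strategy: SearchStrategy, query: str, db: NocDatabase,
                      scope: frozenset[ScopeField] = SCOPE_TITLES_NAMES, *,
                      config: TextConfig = DEFAULT_CONFIG) -> set[str]:
    """Naive re-implementation of the strategy semantics; returns codes.

    Kept deliberately independent of :func:`run_strategy`'s matching
    helpers -- plain loops over every scoped text -- and used as the test
    oracle for strategy equivalence.
    """
    q = " ".join(query.casefold().split())
    q_tokens = "".join(c if (c.isalnum() or c == "_") else " " for c in q).split()
    if strategy is SearchStrategy.MINOR_EXACT:
        q_tokens = [spell_correct(t, db.vocabulary, config.spell_max_distance)
                    for t in q_tokens]
        q = " ".join(q_tokens)
    q_nouns = extract_nouns(q_tokens, config)

    out: set[str] = set()
    for text, codes, _field in _scoped_texts(db, scope):
        t = " ".join(text.casefold().split())
        t_tokens = "".join(c if (c.isalnum() or c == "_") else " " for c in t).split()
        ok = False
        if strategy is SearchStrategy.EXACT:
            ok = q == t
        elif strategy is SearchStrategy.MINOR_EXACT:
            ok = q == t or q_tokens == t_tokens
        elif strategy is SearchStrategy.LIKE:
            ok = q in t
        elif strategy is SearchStrategy.NEAR_SAME_ORDER:
            pos = 0
            found = True
            for tok in q_tokens:
                while pos < len(t_tokens) and t_tokens[pos] != tok:
                    pos += 1
                if pos >= len(t_tokens):
                    found = False
                    break
                pos += 1
            ok = (q in t) or found
        elif strategy is SearchStrategy.NEAR_DIFF_ORDER:
            ok = (q in t) or all(tok in t_tokens for tok in q_tokens)
        elif strategy is SearchStrategy.ANY:
            ok = (q in t) or any(tok in t_tokens for tok in q_tokens)
        elif strategy is SearchStrategy.WEAK:
            ok = any(tok in t_tokens for tok in q_nouns)
        if ok:
            out.update(codes)
    return out
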