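"""Hierarchical candidate filtering: pick one code from many.

When the search cascade returns several candidate unit groups, a single
code is selected by seven ordered narrowing rules that respect the
classification hierarchy.  The job title is matched, in turn, against the
broad-category (skill-type) names, major-group names, minor-group names
and unit-group titles of the candidates; then the industry description is
matched against the candidates' occupational titles, against them again
after symbol splitting (ranked by keyword frequency), and finally against
the unit-group descriptions.  A rule that matches at least one candidate
restricts the survivor set to the matching candidates; a rule that matches
none is skipped, leaving the set unchanged.  Remaining ties are broken by
ascending code, a stable, documented rule.

Rule matching is token containment of the (stemmed) query tokens in the
(stemmed) rule field -- a bare "teacher" therefore matches the minor-group
name "secondary and elementary school teachers and educational
counsellors" despite the plural.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Collection

from .noc import NocDatabase, NocError
from .textprep import (TextConfig, DEFAULT_CONFIG, normalize,
                       split_on_symbols, stem_tokens, tokenize)
from .search import SearchHit

ALL_RULES: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
# the pre-hierarchical-filter variants narrowed by industry only
INDUSTRY_RULES: tuple[int, ...] = (5, 7)

N_FILTER_RULES = 7


@dataclass(frozen=True)
class FilterTrace:
    """Record of a filtering run: which rules applied and what survived."""

    step_reached: int                     # last rule applied (0 = none)
    surviving_codes_per_step: tuple[tuple[int, tuple[str, ...]], ...]
    chosen: str
    tie_broken: bool


def keyword_frequency(keyword: str, corpus_text: str) -> int:
    """Non-overlapping occurrences of the normalized keyword in the corpus."""
    key = normalize(keyword)
    if not key:
        raise NocError("empty keyword")
    corpus = normalize(corpus_text)
    return corpus.count(key)


def _contained(query_tokens: list[str], text: str,
               config: TextConfig) -> bool:
    """All (stemmed) query tokens occur among the (stemmed) text tokens."""
    if not query_tokens:
        return False
    text_tokens = set(stem_tokens(tokenize(text), config))
    return all(t in text_tokens for t in query_tokens)


def filter_candidates(candidates: set[SearchHit] | frozenset[SearchHit],
                      job_title: str, industry: str | None,
                      db: NocDatabase, *,
                      config: TextConfig = DEFAULT_CONFIG,
                      rules: Collection[int] = ALL_RULES,
                      tie_break: str = "ascending",
                      ) -> tuple[str, FilterTrace]:
    """Apply the seven ordered selection rules and return one code.

    The chosen code is always a member of the candidate set; each applied
    rule narrows the survivor set monotonically, and the full trace is
    returned for provenance.
    """
    if not candidates:
        raise NocError("empty candidate set")
    codes = sorted({hit.code for hit in candidates})
    title_tokens = stem_tokens(tokenize(job_title), config) if job_title else []
    industry_tokens = (stem_tokens(tokenize(industry), config)
                       if industry else [])

    def level_name(code: str, length: int) -> str:
        prefix = code[:length]
        try:
            return db.group_name(prefix)
        except NocError:
            return ""

    def unit_texts(code: str) -> str:
        return " ".join(db.unit_groups[code].all_titles)

    steps: list[tuple[int, tuple[str, ...]]] = []
    survivors = codes
    step_reached = 0

    def apply_rule(number: int, matching: list[str]) -> None:
        nonlocal survivors, step_reached
        if matching:
            survivors = matching
            step_reached = number
            steps.append((number, tuple(matching)))

    # rules 1-4: job title against the hierarchy names of the candidates
    for rule_no, length in ((1, 1), (2, 2), (3, 3), (4, 4)):
        if rule_no in rules and title_tokens:
            apply_rule(rule_no, [c for c in survivors
                                 if _contained(title_tokens, level_name(c, length), config)])

    if industry is not None and industry_tokens:
        # rule 5: industry inside the candidates' occupational titles
        if 5 in rules:
            apply_rule(5, [c for c in survivors
                           if any(_contained(industry_tokens, t, config)
                                  for t in db.unit_groups[c].all_titles)])
        # rule 6: split industry parts, rank candidates by keyword frequency
        if 6 in rules:
            parts = split_on_symbols(industry)
            freqs = {c: max(keyword_frequency(p, unit_texts(c)) for p in parts)
                     for c in survivors} if parts else {}
            if freqs and max(freqs.values()) > 0:
                top = max(freqs.values())
                apply_rule(6, [c for c in survivors if freqs[c] == top])
        # rule 7: industry inside the unit-group descriptions
        if 7 in rules:
            apply_rule(7, [c for c in survivors
                           if _contained(industry_tokens,
                                         db.unit_groups[c].description_text, config)])

    chosen = min(survivors) if tie_break == "ascending" else max(survivors)
    trace = FilterTrace(step_reached=step_reached,
                        surviving_codes_per_step=tuple(steps),
                        chosen=chosen, tie_broken=len(survivors) > 1)
    return chosen, trace
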