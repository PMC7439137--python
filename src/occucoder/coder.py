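"""End-to-end occupation coding: from raw free text to one assigned code.

The pipeline escalates through four stages, stopping as soon as any stage
produces candidates:

1. the search cascade on the raw job title (or on the industry when no
   job title was given);
2. on failure, text-repair variants of the job title -- symbol splitting
   (each part tried first in combination with the industry text, the first
   part having priority), stop-word removal, stemming, noun extraction;
3. on failure, the industry description, whole and then split on symbols
   with the parts ranked by keyword frequency;
4. on failure, spelling correction of the job title plus noun extraction,
   then one final search.

Whatever stage produced candidates, a single result is then selected: a
lone candidate is returned directly, several are narrowed by the
hierarchical filter, and none yields an explicitly unassigned record
(never an exception), so that production rate is computable from the
output alone.

Per-generation presets (``PipelineConfig.generation("g0")`` ...
``"g4"``) disable the repair stages each development generation
introduced, so the iterative experiments can be reconstructed; the default
configuration is the final (fourth-generation) behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .noc import NocDatabase, NocError, NocParseError
from .textprep import (TextConfig, DEFAULT_CONFIG, correct_tokens,
                       extract_nouns, normalize, remove_stop_words,
                       split_on_symbols, tokenize)
from .search import (STRATEGY_ORDER, SCOPE_TITLES_NAMES, ScopeField,
                     SearchHit, SearchStrategy, multi_search)
from .filtering import ALL_RULES, INDUSTRY_RULES, FilterTrace, filter_candidates

logger = logging.getLogger(__name__)

_GENERATION_0_STRATEGIES = (SearchStrategy.EXACT, SearchStrategy.LIKE,
                            SearchStrategy.NEAR_DIFF_ORDER, SearchStrategy.ANY)


@dataclass(frozen=True)
class CodingInput:
    """One record to code: free-text job title and/or industry."""

    job_title: str | None = None
    industry: str | None = None
    gold_code: str | None = None

    def __post_init__(self) -> None:
        if not (self.job_title and self.job_title.strip()) and \
                not (self.industry and self.industry.strip()):
            raise NocError("input needs a job title or an industry")
        if self.gold_code is not None and (
                not self.gold_code.isdigit() or len(self.gold_code) != 4):
            raise NocError(f"gold code must be 4 digits: {self.gold_code!r}")


@dataclass(frozen=True)
class CodingResult:
    """An assigned code (or an explicit non-assignment) with provenance."""

    input: CodingInput
    assigned: str | None
    pipeline_step: int | None          # 1-4, stage that produced candidates
    strategy: SearchStrategy | None
    candidates: tuple[SearchHit, ...]  # pre-filter candidate hits
    filter_trace: FilterTrace | None
    corrections: tuple[tuple[str, str], ...] = ()

    @property
    def candidate_codes(self) -> tuple[str, ...]:
        return tuple(sorted({h.code for h in self.candidates}))


@dataclass(frozen=True)
class PipelineConfig:
    """Enablement switches for the pipeline stages and their sub-steps."""

    strategies: tuple[SearchStrategy, ...] = STRATEGY_ORDER
    scope: frozenset[ScopeField] = SCOPE_TITLES_NAMES
    split_titles: bool = True
    combine_title_industry: bool = True
    stop_word_removal: bool = True
    stemming: bool = True
    noun_extraction: bool = True
    industry_fallback: bool = True
    split_industry: bool = True
    industry_frequency_ranking: bool = True
    spell_correction: bool = True
    hierarchical_filter: bool = True
    tie_break: str = "ascending"
    text: TextConfig = DEFAULT_CONFIG
    seed: int | None = None

    @classmethod
    def generation(cls, name: str) -> "PipelineConfig":
        """Preset reconstructing one development generation (g0-g4)."""
        presets = {
            "g0": dict(strategies=_GENERATION_0_STRATEGIES, split_titles=False,
                       combine_title_industry=False, noun_extraction=False,
                       split_industry=False, industry_frequency_ranking=False,
                       spell_correction=False, hierarchical_filter=False),
            "g1": dict(combine_title_industry=False, split_industry=False,
                       industry_frequency_ranking=False,
                       hierarchical_filter=False),
            "g2": dict(combine_title_industry=False,
                       industry_frequency_ranking=False,
                       hierarchical_filter=False),
            "g3": dict(industry_frequency_ranking=False,
                       hierarchical_filter=False),
            "g4": {},
        }
        key = name.lower()
        if key not in presets:
            raise NocError(f"unknown generation preset: {name!r}")
        return cls(**presets[key])  # type: ignore[arg-type]


DEFAULT_PIPELINE = PipelineConfig()


def _first_non_empty(queries: Iterable[str], db: NocDatabase,
                     cfg: PipelineConfig, *, stem: bool = False,
                     ) -> tuple[set[SearchHit], SearchStrategy | None]:
    for query in queries:
        if not normalize(query):
            continue
        hits, strat = multi_search(query, db, cfg.scope, stem=stem,
                                   strategies=cfg.strategies, config=cfg.text)
        if hits:
            return hits, strat
    return set(), None


def _search_split_industry(industry: str, db: NocDatabase,
                           cfg: PipelineConfig,
                           ) -> tuple[set[SearchHit], SearchStrategy | None]:
    """Per-part industry search, parts ranked by keyword frequency."""
    from .filtering import keyword_frequency

    parts = [p for p in split_on_symbols(industry) if p]
    results = []
    for part in parts:
        hits, strat = multi_search(part, db, cfg.scope,
                                   strategies=cfg.strategies, config=cfg.text)
        if hits:
            results.append((part, hits, strat))
    if not results:
        return set(), None
    if not cfg.industry_frequency_ranking or len(results) == 1:
        return results[0][1], results[0][2]

    def part_score(item: tuple[str, set[SearchHit], SearchStrategy]) -> int:
        part, hits, _ = item
        return sum(keyword_frequency(part,
                                     " ".join(db.unit_groups[h.code].all_titles))
                   for h in hits)

    best = max(results, key=part_score)  # ties keep the earliest part
    return best[1], best[2]


def code_record(record: CodingInput, db: NocDatabase,
                cfg: PipelineConfig = DEFAULT_PIPELINE) -> CodingResult:
    """Code a single record; never raises for codable-or-not inputs."""
    title = record.job_title if record.job_title and record.job_title.strip() else None
    industry = record.industry if record.industry and record.industry.strip() else None
    corrections: tuple[tuple[str, str], ...] = ()

    # stage 1: the cascade on the raw primary text
    primary = title if title is not None else industry
    hits, strategy = _first_non_empty([primary], db, cfg)
    step = 1 if hits else None

    # stage 2: text-repair variants of the job title
    if not hits and title is not None:
        variants: list[tuple[list[str], bool]] = []  # (queries, stem?)
        if cfg.split_titles:
            parts = split_on_symbols(title)
            if len(parts) > 1:
                if cfg.combine_title_industry and industry is not None:
                    variants.append(([f"{p} {industry}" for p in parts], False))
                variants.append((parts, False))
        if cfg.stop_word_removal:
            kept = remove_stop_words(tokenize(title), cfg.text)
            if kept and kept != tokenize(title):
                variants.append(([" ".join(kept)], False))
        if cfg.stemming:
            variants.append(([title], True))
        if cfg.noun_extraction:
            nouns = extract_nouns(tokenize(title), cfg.text)
            if nouns and nouns != tokenize(title):
                variants.append(([" ".join(nouns)], False))
        for queries, stem in variants:
            hits, strategy = _first_non_empty(queries, db, cfg, stem=stem)
            if hits:
                step = 2
                break

    # stage 3: the industry description
    if not hits and industry is not None and title is not None and cfg.industry_fallback:
        hits, strategy = _first_non_empty([industry], db, cfg)
        if not hits and cfg.split_industry and len(split_on_symbols(industry)) > 1:
            hits, strategy = _search_split_industry(industry, db, cfg)
        if hits:
            step = 3

    # stage 4: spelling correction of the job title, then nouns
    if not hits and title is not None and cfg.spell_correction:
        pairs = correct_tokens(tokenize(title), db.vocabulary,
                               cfg.text.spell_max_distance)
        corrections = tuple((a, b) for a, b in pairs if a != b)
        if corrections:
            corrected = " ".join(b for _, b in pairs)
            queries = [corrected]
            if cfg.noun_extraction:
                nouns = extract_nouns([b for _, b in pairs], cfg.text)
                if nouns:
                    queries.append(" ".join(nouns))
            hits, strategy = _first_non_empty(queries, db, cfg)
            if hits:
                step = 4

    if not hits:
        logger.debug("unassigned: %r / %r", record.job_title, record.industry)
        return CodingResult(input=record, assigned=None, pipeline_step=None,
                            strategy=None, candidates=(), filter_trace=None,
                            corrections=corrections)

    candidates = tuple(sorted(hits, key=lambda h: (h.code, h.matched_field.value)))
    codes = {h.code for h in hits}
    trace = None
    if len(codes) == 1:
        assigned = next(iter(codes))
    else:
        rules = ALL_RULES if cfg.hierarchical_filter else INDUSTRY_RULES
        assigned, trace = filter_candidates(
            hits, title or "", industry, db, config=cfg.text,
            rules=rules, tie_break=cfg.tie_break)
    logger.debug("assigned %s at step %s via %s (%d candidates)",
                 assigned, step, strategy.name if strategy else None, len(codes))
    return CodingResult(input=record, assigned=assigned, pipeline_step=step,
                        strategy=strategy, candidates=candidates,
                        filter_trace=trace, corrections=corrections)


def code_batch(records: Sequence[CodingInput], db: NocDatabase,
               cfg: PipelineConfig = DEFAULT_PIPELINE,
               ) -> tuple[list[CodingResult], dict]:
    """Code records in order; returns the results and a run report."""
    if not records:
        raise NocError("no records to code")
    results = [code_record(r, db, cfg) for r in records]
    n = len(results)
    n_coded = sum(1 for r in results if r.assigned is not None)
    by_step: dict[int, int] = {}
    by_strategy: dict[str, int] = {}
    for r in results:
        if r.pipeline_step is not None:
            by_step[r.pipeline_step] = by_step.get(r.pipeline_step, 0) + 1
        if r.strategy is not None:
            by_strategy[r.strategy.name] = by_strategy.get(r.strategy.name, 0) + 1
    report = {
        "n_records": n,
        "n_coded": n_coded,
        "production_rate": n_coded / n,
        "by_step": by_step,
        "by_strategy": by_strategy,
    }
    if all(r.input.gold_code is not None for r in results):
        from .evaluation import evaluate
        summary = evaluate(results)
        report["accuracy_at"] = summary.accuracy_at
    return results, report


# ---------------------------------------------------------------------------
# batch file I/O
# ---------------------------------------------------------------------------

INPUT_COLUMNS = ("job_title", "industry", "gold_code")


def read_input_csv(source: TextIO | str,
                   columns: Sequence[str] = INPUT_COLUMNS) -> list[CodingInput]:
    """Read a batch input CSV (job_title, industry, optional gold_code)."""
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    title_col, industry_col, gold_col = columns
    if title_col not in frame.columns and industry_col not in frame.columns:
        raise NocParseError(f"input needs a {title_col!r} or {industry_col!r} column")
    records = []
    for pos, row in enumerate(frame.to_dict("records"), start=2):
        title = str(row.get(title_col, "")).strip() or None
        industry = str(row.get(industry_col, "")).strip() or None
        gold = str(row.get(gold_col, "")).strip() or None
        try:
            records.append(CodingInput(job_title=title, industry=industry,
                                       gold_code=gold))
        except NocError as exc:
            raise NocParseError(f"row {pos}: {exc}") from exc
    if not records:
        raise NocParseError("input contains a header but no rows")
    return records


def write_results_csv(results: Sequence[CodingResult],
                      sink: TextIO | str) -> None:
    """Write coded records with full provenance, mirroring the input order."""
    rows = []
    for r in results:
        rows.append({
            "job_title": r.input.job_title or "",
            "industry": r.input.industry or "",
            "gold_code": r.input.gold_code or "",
            "assigned_code": r.assigned or "",
            "pipeline_step": r.pipeline_step if r.pipeline_step is not None else "",
            "strategy": r.strategy.name if r.strategy is not None else "",
            "n_candidates": len(r.candidate_codes),
            "candidate_codes": ";".join(r.candidate_codes),
            "corrections": ";".join(f"{a}->{b}" for a, b in r.corrections),
            "filter_step_reached": (r.filter_trace.step_reached
                                    if r.filter_trace is not None else ""),
        })
    pd.DataFrame(rows).to_csv(sink, index=False)


def read_results_csv(source: TextIO | str) -> pd.DataFrame:
    """Read back a coded CSV as written by :func:`write_results_csv`."""
    return pd.read_csv(source, dtype=str, keep_default_na=False)
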