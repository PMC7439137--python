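"""Data model and file I/O for the 4-level NOC occupational classification.

The Canadian National Occupational Classification (NOC 2016) arranges
occupations in a four-level hierarchy: 10 broad occupational categories
(1-digit codes), major groups (2 digits), minor groups (3 digits) and unit
groups (4 digits).  Each unit group carries a group title, example
occupational titles, a lead statement, main duties and employment
requirements.  The hierarchy is encoded purely in digit prefixes: the
ancestors of unit group ``0011`` are ``0``, ``00`` and ``001``.

Codes are digit *strings*, never integers -- ``"0011"`` must not collapse
to ``11``.

The on-disk representation is a single delimited text file (a "database
dump"): one row per group at any level, with the descriptive fields
populated only for unit groups.  :class:`DumpDialect` configures column
names and delimiters; the shipped default matches :func:`write_noc_dump`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .textprep import normalize, tokenize

LEVEL_NAMES = {1: "broad category", 2: "major group", 3: "minor group", 4: "unit group"}


class NocError(ValueError):
    """Domain error for classification handling."""


class NocParseError(NocError):
    """A dump row could not be parsed."""


class NocValidationError(NocError):
    """A loaded classification violates a structural invariant."""


def _check_code(code: str, *, lengths: tuple[int, ...] = (1, 2, 3, 4)) -> str:
    if not isinstance(code, str) or not code.isdigit() or len(code) not in lengths:
        raise NocError(f"invalid NOC code: {code!r}")
    return code


def ancestors(code: str) -> list[str]:
    """Strict digit-prefixes of a code, shortest first.

    >>> ancestors("0011")
    ['0', '00', '001']
    """
    _check_code(code)
    return [code[:i] for i in range(1, len(code))]


@dataclass(frozen=True)
class GroupName:
    """A named group at level 1, 2 or 3."""

    code: str
    name: str

    def __post_init__(self) -> None:
        _check_code(self.code, lengths=(1, 2, 3))
        if not self.name:
            raise NocError(f"group {self.code}: empty name")


@dataclass(frozen=True)
class UnitGroup:
    """A 4-digit leaf group bundling similar occupational titles."""

    code: str
    group_title: str
    example_titles: tuple[str, ...] = ()
    lead_statement: str = ""
    main_duties: str = ""
    employment_requirements: str = ""

    def __post_init__(self) -> None:
        _check_code(self.code, lengths=(4,))

    @property
    def description_text(self) -> str:
        """Lead statement, main duties and employment requirements, joined."""
        return " ".join(t for t in (self.lead_statement, self.main_duties,
                                    self.employment_requirements) if t)

    @property
    def all_titles(self) -> tuple[str, ...]:
        """The group title followed by the example occupational titles."""
        seen = {normalize(self.group_title)}
        extra = []
        for t in self.example_titles:
            if normalize(t) not in seen:
                seen.add(normalize(t))
                extra.append(t)
        return (self.group_title, *extra)


@dataclass
class NocDatabase:
    """The full 4-level classification with search indexes.

    ``title_index`` maps normalized occupational titles (example titles and
    unit-group titles) to the set of 4-digit codes carrying them;
    ``vocabulary`` maps tokens to corpus frequencies over all titles, group
    names and descriptions and is the candidate pool for spelling
    correction.
    """

    broad_categories: dict[str, GroupName]
    major_groups: dict[str, GroupName]
    minor_groups: dict[str, GroupName]
    unit_groups: dict[str, UnitGroup]
    title_index: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    vocabulary: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.title_index and not self.vocabulary:
            self.rebuild_indexes()

    # -- index construction ---------------------------------------------
    def rebuild_indexes(self) -> None:
        index: dict[str, set[str]] = {}
        vocab: dict[str, int] = {}

        def count(text: str) -> None:
            for tok in tokenize(text):
                vocab[tok] = vocab.get(tok, 0) + 1

        for unit in self.unit_groups.values():
            for title in unit.all_titles:
                index.setdefault(normalize(title), set()).add(unit.code)
                count(title)
            count(unit.description_text)
        for level in (self.broad_categories, self.major_groups, self.minor_groups):
            for group in level.values():
                count(group.name)
        self.title_index = {k: frozenset(v) for k, v in index.items()}
        self.vocabulary = vocab

    # -- convenience accessors ------------------------------------------
    def group_name(self, code: str) -> str:
        level = {1: self.broad_categories, 2: self.major_groups,
                 3: self.minor_groups}.get(len(code))
        if level is not None and code in level:
            return level[code].name
        if code in self.unit_groups:
            return self.unit_groups[code].group_title
        raise NocError(f"unknown code: {code!r}")

    def descendants(self, code: str) -> list[str]:
        """Unit-group codes under a (possibly internal) code."""
        _check_code(code)
        return sorted(c for c in self.unit_groups if c.startswith(code))

    def lookup_title(self, title: str) -> frozenset[str]:
        return self.title_index.get(normalize(title), frozenset())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NocDatabase):
            return NotImplemented
        return (self.broad_categories == other.broad_categories
                and self.major_groups == other.major_groups
                and self.minor_groups == other.minor_groups
                and self.unit_groups == other.unit_groups)


def validate(db: NocDatabase) -> list[str]:
    """Report every structural violation; an empty list means valid."""
    problems: list[str] = []
    levels: Mapping[int, Mapping[str, object]] = {
        1: db.broad_categories, 2: db.major_groups,
        3: db.minor_groups, 4: db.unit_groups,
    }
    for length, groups in levels.items():
        for code in groups:
            if len(code) != length or not code.isdigit():
                problems.append(f"{code}: malformed code at level {length}")
    seen: dict[str, int] = {}
    for length, groups in levels.items():
        for code in groups:
            if code in seen:
                problems.append(f"{code}: duplicate code (levels {seen[code]} and {length})")
            seen[code] = length
    for code, unit in db.unit_groups.items():
        for anc in ancestors(code):
            if anc not in levels[len(anc)]:
                problems.append(f"{code}: orphan unit group, missing ancestor {anc}")
        if not unit.example_titles:
            problems.append(f"{code}: unit group has no example titles")
    expected_titles = {normalize(t) for u in db.unit_groups.values() for t in u.all_titles}
    if set(db.title_index) != expected_titles:
        problems.append("title_index does not cover exactly the example and group titles")
    for tok, freq in db.vocabulary.items():
        if not isinstance(freq, int) or freq <= 0:
            problems.append(f"vocabulary[{tok!r}]: non-positive frequency {freq!r}")
    return problems


# ---------------------------------------------------------------------------
# dump I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DumpDialect:
    """Column names and delimiters of the classification dump file."""

    delimiter: str = ","
    title_separator: str = ";"
    level_col: str = "level"
    code_col: str = "code"
    name_col: str = "name"
    titles_col: str = "example_titles"
    lead_col: str = "lead_statement"
    duties_col: str = "main_duties"
    requirements_col: str = "employment_requirements"

    @property
    def columns(self) -> list[str]:
        return [self.level_col, self.code_col, self.name_col, self.titles_col,
                self.lead_col, self.duties_col, self.requirements_col]


DEFAULT_DIALECT = DumpDialect()

_RANGE_SEP = "-"


def _expand_range(code: str) -> list[str]:
    """Expand a printed major-group range like ``01-05`` into 01..05."""
    lo, hi = code.split(_RANGE_SEP, 1)
    lo, hi = lo.strip(), hi.strip()
    if not (lo.isdigit() and hi.isdigit() and len(lo) == len(hi) == 2 and lo <= hi):
        raise NocParseError(f"bad major-group range: {code!r}")
    width = len(lo)
    return [str(n).zfill(width) for n in range(int(lo), int(hi) + 1)]


def load_noc_dump(source: TextIO | str,
                  dialect: DumpDialect = DEFAULT_DIALECT) -> NocDatabase:
    """Read a classification dump and return a validated :class:`NocDatabase`.

    Raises :class:`NocParseError` on malformed rows and
    :class:`NocValidationError` when the hierarchy invariants fail
    (duplicate codes, orphan unit groups, ...).
    """
    try:
        frame = pd.read_csv(source, sep=dialect.delimiter, dtype=str,
                            keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise NocParseError("empty dump stream") from exc
    missing = [c for c in dialect.columns if c not in frame.columns]
    if missing:
        raise NocParseError(f"dump is missing columns: {missing}")
    if frame.empty:
        raise NocParseError("dump contains a header but no rows")

    levels: dict[int, dict[str, GroupName]] = {1: {}, 2: {}, 3: {}}
    units: dict[str, UnitGroup] = {}

    def add_group(level: int, code: str, name: str, row_no: int) -> None:
        if code in levels[level]:
            raise NocValidationError(f"row {row_no}: duplicate code {code}")
        levels[level][code] = GroupName(code=code, name=name)

    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(frame.columns, row))
        raw_level = str(rec[dialect.level_col]).strip()
        code = str(rec[dialect.code_col]).strip()
        name = str(rec[dialect.name_col]).strip()
        if raw_level not in {"1", "2", "3", "4"}:
            raise NocParseError(f"row {pos}: bad level {raw_level!r}")
        level = int(raw_level)
        try:
            if level == 2 and _RANGE_SEP in code:
                for expanded in _expand_range(code):
                    add_group(2, expanded, name, pos)
                continue
            if level < 4:
                if len(code) != level or not code.isdigit():
                    raise NocParseError(f"row {pos}: code {code!r} does not fit level {level}")
                add_group(level, code, name, pos)
                continue
            if len(code) != 4 or not code.isdigit():
                raise NocParseError(f"row {pos}: code {code!r} does not fit level 4")
            if code in units:
                raise NocValidationError(f"row {pos}: duplicate code {code}")
            raw_titles = str(rec[dialect.titles_col])
            titles = tuple(t.strip() for t in raw_titles.split(dialect.title_separator)
                           if t.strip())
            units[code] = UnitGroup(
                code=code, group_title=name,
                example_titles=titles or (name,),
                lead_statement=str(rec[dialect.lead_col]).strip(),
                main_duties=str(rec[dialect.duties_col]).strip(),
                employment_requirements=str(rec[dialect.requirements_col]).strip(),
            )
        except NocError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise NocParseError(f"row {pos}: {exc}") from exc

    db = NocDatabase(broad_categories=levels[1], major_groups=levels[2],
                     minor_groups=levels[3], unit_groups=units)
    problems = validate(db)
    if problems:
        raise NocValidationError("; ".join(problems))
    return db


def write_noc_dump(db: NocDatabase, sink: TextIO | str,
                   dialect: DumpDialect = DEFAULT_DIALECT) -> None:
    """Serialize a database so that :func:`load_noc_dump` reproduces it."""
    rows: list[dict[str, str]] = []

    def group_row(level: int, group: GroupName) -> dict[str, str]:
        return {dialect.level_col: str(level), dialect.code_col: group.code,
                dialect.name_col: group.name, dialect.titles_col: "",
                dialect.lead_col: "", dialect.duties_col: "",
                dialect.requirements_col: ""}

    for level, groups in ((1, db.broad_categories), (2, db.major_groups),
                          (3, db.minor_groups)):
        for code in sorted(groups):
            rows.append(group_row(level, groups[code]))
    for code in sorted(db.unit_groups):
        unit = db.unit_groups[code]
        for title in unit.example_titles:
            if dialect.title_separator in title:
                raise NocError(
                    f"{code}: example title contains the title separator "
                    f"{dialect.title_separator!r}: {title!r}")
        rows.append({
            dialect.level_col: "4", dialect.code_col: unit.code,
            dialect.name_col: unit.group_title,
            dialect.titles_col: dialect.title_separator.join(unit.example_titles),
            dialect.lead_col: unit.lead_statement,
            dialect.duties_col: unit.main_duties,
            dialect.requirements_col: unit.employment_requirements,
        })
    frame = pd.DataFrame(rows, columns=dialect.columns)
    frame.to_csv(sink, sep=dialect.delimiter, index=False)


def dumps_noc(db: NocDatabase, dialect: DumpDialect = DEFAULT_DIALECT) -> str:
    """Serialized dump as a string (round-trip and fixture helper)."""
    buf = io.StringIO()
    write_noc_dump(db, buf, dialect)
    return buf.getvalue()
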