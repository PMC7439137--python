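"""Fixtures and synthetic data: mini-classification, random classifications
and noisy coding inputs with known gold codes.

Three generators make every pipeline stage testable without downloading
the real classification:

* :func:`build_inpaper_fixture` -- the miniature NOC assembled from the
  published excerpts: the 10 broad occupational categories, the senior-
  management branch (00 / 001 / 0011-0016) and the education-services
  branch (40 / 403 / 4031-4033), titles verbatim.
* :func:`generate_synthetic_noc` -- a random hierarchically consistent
  classification built from a curated occupational vocabulary.  Distinct
  vocabulary words are kept at Damerau-Levenshtein distance >= 3 from one
  another and generated titles are globally unique, so zero-noise inputs
  are recovered exactly and single-typo spelling correction is well-posed.
  Title collisions across unit groups (present in the real NOC) are
  injected only via the explicit ``collision_rate`` switch.
* :func:`generate_inputs` -- noisy coding inputs whose pathologies mirror
  the ones observed in real survey answers: typographical errors
  ("CONSTUCTION"), slash-joined compound titles ("Bartender/waiter"),
  adjective prefixes ("certified accountant") and case scrambling.

All generation is deterministic in its seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from importlib import resources

from .coder import CodingInput
from .noc import (GroupName, NocDatabase, NocError, UnitGroup, load_noc_dump)

# -- curated vocabulary: pairwise Damerau-Levenshtein distance >= 3 ---------

ROLE_WORDS = (
    "manager technician operator supervisor engineer analyst coordinator "
    "inspector consultant electrician plumber carpenter welder machinist "
    "designer developer librarian pharmacist therapist accountant auditor "
    "translator bartender housekeeper landscaper journalist economist "
    "geologist chemist surveyor dispatcher estimator paralegal optician "
    "dietitian archivist curator firefighter veterinarian cartographer "
    "brewer roofer glazier upholsterer").split()

MODIFIER_WORDS = (
    "senior chief regional municipal industrial agricultural clinical "
    "forestry marine petroleum culinary graphic pediatric aerospace digital "
    "financial maritime orthopedic automotive hydraulic geothermal "
    "residential commercial environmental pharmaceutical").split()

SECTOR_WORDS = (
    "education health construction transportation manufacturing utilities "
    "farming finance hospitality telecommunications mining fisheries "
    "broadcasting insurance logistics tourism energy retail").split()

FILLER_WORDS = (
    "occupations services workers duties employers perform related require "
    "training certification tasks settings organize maintain prepare").split()

# prefixes injected by adjective noise; deliberately NOT part of the
# classification vocabulary, like "certified" in "certified accountant"
NOISE_ADJECTIVES = ("certified", "experienced", "licensed", "registered",
                    "qualified", "freelance", "parttime", "seasonal")

VOCABULARY_WORDS = tuple(ROLE_WORDS + MODIFIER_WORDS + SECTOR_WORDS + FILLER_WORDS)


def build_inpaper_fixture() -> NocDatabase:
    """The miniature classification shipped with the package.

    Contains exactly the 10 broad categories plus the two fully worked
    branches of the published excerpts; unit groups carry their group
    title as their sole example title.
    """
    with resources.files("occucoder.data").joinpath("noc_mini.csv").open(
            "r", encoding="utf-8") as handle:
        return load_noc_dump(handle)


@dataclass(frozen=True)
class NoiseConfig:
    """Input-noise model for :func:`generate_inputs`.

    Rates are per-record probabilities; ``max_edits`` bounds the number of
    random character edits applied when a typo is injected.  Defaults
    emulate moderately dirty survey free text: occasional typos and
    compounds, frequent case scrambling.
    """

    typo_rate: float = 0.15
    max_edits: int = 1
    slash_compound_rate: float = 0.10
    adjective_rate: float = 0.15
    case_scramble_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("typo_rate", "slash_compound_rate", "adjective_rate",
                     "case_scramble_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise NocError(f"{name} must be in [0, 1], got {value}")
        if self.max_edits < 1:
            raise NocError("max_edits must be >= 1")


ZERO_NOISE = NoiseConfig(typo_rate=0.0, slash_compound_rate=0.0,
                         adjective_rate=0.0, case_scramble_rate=0.0)


def generate_synthetic_noc(seed: int, n_major: int = 4,
                           n_minor_per_major: int = 3,
                           n_units_per_minor: int = 5,
                           titles_per_unit: int = 4,
                           collision_rate: float = 0.0) -> NocDatabase:
    """A random valid classification, deterministic in ``seed``.

    Major groups are spread across broad categories; minor and unit codes
    extend their parent by one digit.  Raises when the requested counts
    exceed the digit code space or the unique-title budget.
    """
    if min(n_major, n_minor_per_major, n_units_per_minor, titles_per_unit) < 1:
        raise NocError("all counts must be >= 1")
    if n_major > 100:
        raise NocError("at most 100 major groups fit two digits")
    if n_minor_per_major > 10 or n_units_per_minor > 10:
        raise NocError("at most 10 children fit one extra digit")
    n_minors = n_major * n_minor_per_major
    n_units = n_minors * n_units_per_minor
    # minor-group names and unit groups each draw from the unique-pair pool
    n_titles = n_minors + n_units * (titles_per_unit + 1)
    pool_size = len(MODIFIER_WORDS) * len(ROLE_WORDS)
    if n_titles > pool_size:
        raise NocError(f"requested {n_titles} unique titles; "
                       f"vocabulary supports {pool_size}")

    rng = random.Random(seed)
    pairs = list(itertools.product(MODIFIER_WORDS, ROLE_WORDS))
    rng.shuffle(pairs)
    pair_iter = iter(pairs)

    broad: dict[str, GroupName] = {}
    majors: dict[str, GroupName] = {}
    minors: dict[str, GroupName] = {}
    units: dict[str, UnitGroup] = {}
    sectors = list(SECTOR_WORDS)
    rng.shuffle(sectors)

    def next_title() -> str:
        modifier, role = next(pair_iter)
        return f"{modifier} {role}"

    for m in range(n_major):
        major_code = f"{m % 10}{m // 10}"
        category = major_code[0]
        if category not in broad:
            sector = sectors[int(category) % len(sectors)]
            broad[category] = GroupName(
                code=category, name=f"occupations in {sector}")
        majors[major_code] = GroupName(
            code=major_code,
            name=f"{rng.choice(MODIFIER_WORDS)} occupations in "
                 f"{sectors[m % len(sectors)]}")
        for mi in range(n_minor_per_major):
            minor_code = f"{major_code}{mi}"
            minors[minor_code] = GroupName(
                code=minor_code,
                name=f"{next_title()}s and {rng.choice(FILLER_WORDS)}")
            for u in range(n_units_per_minor):
                unit_code = f"{minor_code}{u}"
                group_title = next_title()
                titles = [next_title() for _ in range(titles_per_unit)]
                sector = sectors[m % len(sectors)]
                lead = (f"this unit group includes {titles[0]}s and related "
                        f"workers in {sector} settings")
                duties = (f"{group_title}s perform {rng.choice(FILLER_WORDS)} "
                          f"and {rng.choice(FILLER_WORDS)} duties")
                reqs = (f"employers require {rng.choice(FILLER_WORDS)} and "
                        f"{rng.choice(FILLER_WORDS)} training")
                units[unit_code] = UnitGroup(
                    code=unit_code, group_title=group_title,
                    example_titles=tuple(titles), lead_statement=lead,
                    main_duties=duties, employment_requirements=reqs)

    if collision_rate > 0.0:
        codes = sorted(units)
        for code in codes:
            if rng.random() < collision_rate and len(codes) > 1:
                other = rng.choice([c for c in codes if c != code])
                stolen = rng.choice(units[other].example_titles)
                unit = units[code]
                units[code] = UnitGroup(
                    code=unit.code, group_title=unit.group_title,
                    example_titles=unit.example_titles + (stolen,),
                    lead_statement=unit.lead_statement,
                    main_duties=unit.main_duties,
                    employment_requirements=unit.employment_requirements)

    return NocDatabase(broad_categories=broad, major_groups=majors,
                       minor_groups=minors, unit_groups=units)


# -- noise injection ---------------------------------------------------------

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _random_edit(rng: random.Random, text: str) -> str:
    """One random character edit (substitute/transpose/delete/insert),
    applied at a letter position so word boundaries survive."""
    positions = [i for i, c in enumerate(text) if c.isalpha()]
    if not positions:
        return text
    op = rng.choice(("substitute", "transpose", "delete", "insert"))
    i = rng.choice(positions)
    if op == "substitute":
        repl = rng.choice([c for c in _LETTERS if c != text[i].lower()])
        return text[:i] + repl + text[i + 1:]
    if op == "transpose":
        if i + 1 < len(text) and text[i + 1].isalpha():
            return text[:i] + text[i + 1] + text[i] + text[i + 2:]
        if i >= 1 and text[i - 1].isalpha():
            return text[:i - 1] + text[i] + text[i - 1] + text[i + 1:]
        return text
    if op == "delete":
        return text[:i] + text[i + 1:]
    return text[:i] + rng.choice(_LETTERS) + text[i:]


def _apply_noise(rng: random.Random, title: str, alt_title: str | None,
                 noise: NoiseConfig) -> str:
    text = title
    if alt_title is not None and rng.random() < noise.slash_compound_rate:
        text = f"{text}/{alt_title}"
    if rng.random() < noise.adjective_rate:
        text = f"{rng.choice(NOISE_ADJECTIVES)} {text}"
    if rng.random() < noise.typo_rate:
        for _ in range(rng.randint(1, noise.max_edits)):
            text = _random_edit(rng, text)
    if rng.random() < noise.case_scramble_rate:
        text = text.upper()
    return text


def generate_inputs(db: NocDatabase, n: int,
                    noise: NoiseConfig = NoiseConfig()) -> list[CodingInput]:
    """Draw ``n`` noisy coding inputs with known gold codes.

    Each record's job title derives from a sampled example title of a
    sampled unit group (the gold code); the industry is the name of the
    gold code's broad category.  Slash compounds append a title from a
    different unit group, the gold code staying with the first part.
    """
    if n < 1:
        raise NocError("n must be >= 1")
    rng = random.Random(noise.seed)
    codes = sorted(db.unit_groups)
    records = []
    for _ in range(n):
        code = rng.choice(codes)
        unit = db.unit_groups[code]
        title = rng.choice(list(unit.example_titles))
        alt = None
        if len(codes) > 1:
            other = db.unit_groups[rng.choice([c for c in codes if c != code])]
            alt = rng.choice(list(other.example_titles))
        job_title = _apply_noise(rng, title, alt, noise)
        industry = db.broad_categories[code[0]].name
        if rng.random() < noise.case_scramble_rate:
            industry = industry.upper()
        records.append(CodingInput(job_title=job_title, industry=industry,
                                   gold_code=code))
    return records
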