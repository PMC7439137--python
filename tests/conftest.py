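import random

import pytest
from hypothesis import settings

from occucoder import (CodingInput, GroupName, NocDatabase, UnitGroup,
                       build_inpaper_fixture, generate_synthetic_noc)

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_db() -> NocDatabase:
    """The in-package miniature classification (Box 1 / Box 2 / Table 1)."""
    return build_inpaper_fixture()


@pytest.fixture(scope="session")
def synthetic_db() -> NocDatabase:
    """Deterministic random classification used across oracle tests."""
    return generate_synthetic_noc(seed=1)


@pytest.fixture(scope="session")
def table2_db() -> NocDatabase:
    """A tiny classification carrying the three example survey titles."""
    units = {
        "0213": UnitGroup("0213", "computer and information systems managers",
                          ("managing website", "information systems manager")),
        "0311": UnitGroup("0311", "managers in health care",
                          ("manager", "health care manager")),
        "0651": UnitGroup("0651", "managers in customer and personal services",
                          ("owner of cleaning business", "cleaning supervisor")),
    }
    broad = {"0": GroupName("0", "management occupations")}
    majors = {"02": GroupName("02", "specialized middle management occupations"),
              "03": GroupName("03", "managers in health care"),
              "06": GroupName("06", "middle management occupations in sales")}
    minors = {"021": GroupName("021", "managers in engineering and information systems"),
              "031": GroupName("031", "managers in health care"),
              "065": GroupName("065", "managers in customer and personal services")}
    return NocDatabase(broad_categories=broad, major_groups=majors,
                       minor_groups=minors, unit_groups=units)


def random_queries(db: NocDatabase, n: int, seed: int) -> list[str]:
    """Realistically messy queries derived from the database's own text."""
    rng = random.Random(seed)
    texts = [t for u in db.unit_groups.values() for t in u.all_titles]
    texts += [g.name for level in (db.broad_categories, db.major_groups,
                                   db.minor_groups) for g in level.values()]
    queries = []
    while len(queries) < n:
        tokens = rng.choice(texts).split()
        kind = rng.randrange(6)
        if kind == 0:          # verbatim text
            q = " ".join(tokens)
        elif kind == 1:        # token subset, order kept
            keep = sorted(rng.sample(range(len(tokens)),
                                     rng.randint(1, len(tokens))))
            q = " ".join(tokens[i] for i in keep)
        elif kind == 2:        # shuffled tokens
            shuffled = tokens[:]
            rng.shuffle(shuffled)
            q = " ".join(shuffled)
        elif kind == 3:        # one token with a typo
            tok = list(rng.choice(tokens))
            i = rng.randrange(len(tok))
            tok[i] = rng.choice("abcdefghijklmnopqrstuvwxyz")
            q = "".join(tok)
        elif kind == 4:        # slash compound of two texts
            q = rng.choice(texts) + "/" + rng.choice(texts)
        else:                  # tokens from two different texts
            q = (rng.choice(tokens) + " "
                 + rng.choice(rng.choice(texts).split()))
        if q.strip():
            queries.append(q)
    return queries


def make_inputs_for(db: NocDatabase) -> list[CodingInput]:
    """One verbatim input per unit group, gold = that group."""
    return [CodingInput(job_title=u.example_titles[0], gold_code=u.code)
            for u in db.unit_groups.values()]
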