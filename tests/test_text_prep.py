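"""Text repair primitives: normalization, splitting, stemming, correction."""

import pytest
from hypothesis import given, strategies as st

from occucoder import (extract_nouns, normalize, remove_stop_words,
                       spell_correct, split_on_symbols, stem_tokens, tokenize)
from occucoder._distance import damerau_levenshtein
from occucoder._porter import porter_stem


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("MARKETING IN MD OFFICE", "marketing in md office"),
        ("  Manager ", "manager"),
        ("Owner  of\tcleaning   business", "owner of cleaning business"),
    ])
    def test_examples(self, raw, expected):
        assert normalize(raw) == expected

    @given(st.text(max_size=40))
    def test_idempotent(self, text):
        assert normalize(normalize(text)) == normalize(text)


class TestSplitOnSymbols:
    @pytest.mark.parametrize("raw,expected", [
        ("Bartender/waiter", ["bartender", "waiter"]),
        ("Interpretor/Translator", ["interpretor", "translator"]),
        ("manager", ["manager"]),
        ("real estate/housing", ["real estate", "housing"]),
        ("self-employed, cleaner", ["self", "employed", "cleaner"]),
    ])
    def test_examples(self, raw, expected):
        assert split_on_symbols(raw) == expected

    def test_parts_are_normalized_and_non_empty(self):
        assert split_on_symbols("A//B--") == ["a", "b"]


class TestStopWords:
    def test_shipped_list_drops_of(self):
        assert remove_stop_words(["owner", "of", "cleaning", "business"]) == \
            ["owner", "cleaning", "business"]

    def test_empty_and_stopfree_inputs(self):
        assert remove_stop_words([]) == []
        assert remove_stop_words(["cleaning", "business"]) == \
            ["cleaning", "business"]

    @given(st.lists(st.text(alphabet="abcdefof", min_size=1, max_size=6),
                    max_size=8))
    def test_result_is_a_subsequence(self, tokens):
        kept = remove_stop_words(tokens)
        it = iter(tokens)
        assert all(tok in it for tok in kept)


# Expected stems from the published example vocabulary of the suffix-
# stripping algorithm (whole-algorithm outputs).
PORTER_PAIRS = [
    ("caresses", "caress"), ("ponies", "poni"), ("ties", "ti"),
    ("caress", "caress"), ("cats", "cat"), ("feed", "feed"),
    ("agreed", "agre"), ("plastered", "plaster"), ("bled", "bled"),
    ("motoring", "motor"), ("sing", "sing"), ("conflated", "conflat"),
    ("troubled", "troubl"), ("sized", "size"), ("hopping", "hop"),
    ("tanned", "tan"), ("falling", "fall"), ("hissing", "hiss"),
    ("fizzed", "fizz"), ("failing", "fail"), ("filing", "file"),
    ("happy", "happi"), ("sky", "sky"), ("relational", "relat"),
    ("conditional", "condit"), ("rational", "ration"),
    ("digitizer", "digit"), ("managing", "manag"), ("teacher", "teacher"),
    ("teachers", "teacher"), ("occupations", "occup"),
    ("generalization", "gener"), ("oscillate", "oscil"), ("roll", "roll"),
]


class TestStemming:
    @pytest.mark.parametrize("word,stem", PORTER_PAIRS)
    def test_against_published_vocabulary(self, word, stem):
        assert porter_stem(word) == stem

    def test_stem_tokens_maps_elementwise(self):
        assert stem_tokens(["managing", "teachers"]) == ["manag", "teacher"]

    def test_conflates_singular_and_plural_forms(self):
        # matching stems query and index exactly once each; what matters is
        # that inflected variants land on the same stem
        for singular, plural in [("teacher", "teachers"),
                                 ("manager", "managers"),
                                 ("counsellor", "counsellors"),
                                 ("technician", "technicians")]:
            assert porter_stem(plural) == porter_stem(singular)

    def test_derivational_chains_terminate_within_two_passes(self, synthetic_db):
        # suffix stripping is not idempotent on derivational chains
        # ("environmental" -> "environment" -> "environ"), but every chain
        # over the occupational vocabulary reaches a fixed point quickly
        for token in synthetic_db.vocabulary:
            twice = porter_stem(porter_stem(token))
            assert porter_stem(twice) == twice


class TestExtractNouns:
    @pytest.mark.parametrize("tokens,expected", [
        (["agricultural", "producer"], ["producer"]),
        (["certified", "accountant"], ["accountant"]),
        (["manager"], ["manager"]),
        ([], []),
    ])
    def test_examples(self, tokens, expected):
        assert extract_nouns(tokens) == expected

    def test_never_empty_for_nonempty_input(self):
        # every token looks adjectival -> fall back to the last token
        assert extract_nouns(["clinical", "industrial"]) == ["industrial"]

    @given(st.lists(st.text(alphabet="abcdeilmnorst", min_size=1, max_size=10),
                    min_size=1, max_size=6))
    def test_result_is_subset_of_tokens(self, tokens):
        assert set(extract_nouns(tokens)) <= set(tokens)


import functools


@functools.lru_cache(maxsize=None)
def _brute_dl(a: str, b: str) -> int:
    """Recursive Damerau-Levenshtein oracle, straight from the definition."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    costs = [_brute_dl(a[1:], b) + 1, _brute_dl(a, b[1:]) + 1,
             _brute_dl(a[1:], b[1:]) + (a[0] != b[0])]
    if len(a) > 1 and len(b) > 1 and a[0] == b[1] and a[1] == b[0]:
        costs.append(_brute_dl(a[2:], b[2:]) + 1)
    return min(costs)


class TestSpellCorrect:
    VOCAB = {"construction": 9, "accountant": 5, "manager": 7, "teacher": 4}

    @pytest.mark.parametrize("typo,corrected", [
        ("constuction", "construction"),
        ("accontant", "accountant"),
        ("manager", "manager"),        # already in vocabulary
        ("xyzzyplugh", "xyzzyplugh"),  # nothing within range
    ])
    def test_examples(self, typo, corrected):
        assert spell_correct(typo, self.VOCAB, 2) == corrected

    def test_frequency_breaks_candidate_ties(self):
        vocab = {"cat": 2, "car": 9}
        assert spell_correct("caq", vocab, 1) == "car"
        assert spell_correct("caq", {"cat": 3, "car": 3}, 1) == "car"  # lexicographic

    @given(st.text(alphabet="abcd", max_size=5), st.text(alphabet="abcd", max_size=5))
    def test_dp_distance_matches_brute_force(self, a, b):
        assert damerau_levenshtein(a, b) == _brute_dl(a, b)

    @given(st.text(alphabet="abcdef", min_size=1, max_size=7))
    def test_never_returns_a_farther_token(self, token):
        result = spell_correct(token, self.VOCAB, 2)
        if result != token:
            assert _brute_dl(token, result) <= 2

    def test_edlib_levenshtein_bounds_from_above(self, synthetic_db):
        # Levenshtein (no transpositions) can never be below DL, and a
        # transposition costs at most two Levenshtein edits
        import edlib
        words = sorted(synthetic_db.vocabulary)[:40]
        for a, b in zip(words, reversed(words)):
            lev = edlib.align(a, b)["editDistance"]
            dl = damerau_levenshtein(a, b)
            assert dl <= lev <= 2 * dl
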