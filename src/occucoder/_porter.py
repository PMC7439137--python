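"""Porter suffix-stripping stemmer.

A self-contained implementation of the classic five-step Porter algorithm
(the original 1980 formulation, without later revisions).  It is used to
conflate morphological variants of occupational vocabulary -- "teachers"
and "teacher", "managing" and "management" both stem to comparable forms --
so that token-level matching survives plural and derivational endings.

The implementation operates on lowercase ASCII words; tokens shorter than
three characters are returned unchanged, as the algorithm prescribes.
"""

from __future__ import annotations

_VOWELS = "aeiou"


class _Stemmer:
    """Single-word stemming state machine."""

    def __init__(self, word: str) -> None:
        self.b = word
        self.k = len(word) - 1  # index of last letter of current stem
        self.j = 0              # general offset set by ends()

    # -- letter classification ------------------------------------------
    def _cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self._cons(i - 1)
        return True

    def _m(self) -> int:
        """Measure: number of VC sequences in b[0..j]."""
        n = i = 0
        while True:
            if i > self.j:
                return n
            if not self._cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > self.j:
                    return n
                if self._cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > self.j:
                    return n
                if not self._cons(i):
                    break
                i += 1
            i += 1

    def _vowel_in_stem(self) -> bool:
        return any(not self._cons(i) for i in range(self.j + 1))

    def _double_c(self, i: int) -> bool:
        return i >= 1 and self.b[i] == self.b[i - 1] and self._cons(i)

    def _cvc(self, i: int) -> bool:
        # consonant-vowel-consonant ending where the final consonant is
        # not w, x or y -- the *o condition of the algorithm
        if i < 2 or not self._cons(i) or self._cons(i - 1) or not self._cons(i - 2):
            return False
        return self.b[i] not in "wxy"

    # -- suffix machinery -----------------------------------------------
    def _ends(self, s: str) -> bool:
        ln = len(s)
        if ln > self.k + 1 or self.b[self.k - ln + 1 : self.k + 1] != s:
            return False
        self.j = self.k - ln
        return True

    def _set_to(self, s: str) -> None:
        self.b = self.b[: self.j + 1] + s
        self.k = self.j + len(s)

    def _r(self, s: str) -> None:
        if self._m() > 0:
            self._set_to(s)

    # -- the five steps --------------------------------------------------
    def _step1ab(self) -> None:
        if self.b[self.k] == "s":
            if self._ends("sses"):
                self.k -= 2
            elif self._ends("ies"):
                self._set_to("i")
            elif self.b[self.k - 1] != "s":
                self.k -= 1
        if self._ends("eed"):
            if self._m() > 0:
                self.k -= 1
        elif (self._ends("ed") or self._ends("ing")) and self._vowel_in_stem():
            self.k = self.j
            if self._ends("at"):
                self._set_to("ate")
            elif self._ends("bl"):
                self._set_to("ble")
            elif self._ends("iz"):
                self._set_to("ize")
            elif self._double_c(self.k):
                if self.b[self.k] not in "lsz":
                    self.k -= 1
            else:
                self.j = self.k
                if self._m() == 1 and self._cvc(self.k):
                    self._set_to("e")

    def _step1c(self) -> None:
        # y -> i only when preceded by a consonant (the common revision of
        # the original rule; keeps the step idempotent on words like
        # "employ" while still conflating "happy"/"happiness")
        if (self._ends("y") and self._vowel_in_stem()
                and self.k > 0 and self._cons(self.k - 1)):
            self.b = self.b[: self.k] + "i"

    _STEP2 = [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
        ("anci", "ance"), ("izer", "ize"), ("abli", "able"), ("alli", "al"),
        ("entli", "ent"), ("eli", "e"), ("ousli", "ous"), ("ization", "ize"),
        ("ation", "ate"), ("ator", "ate"), ("alism", "al"),
        ("iveness", "ive"), ("fulness", "ful"), ("ousness", "ous"),
        ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ]

    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]

    def _map_suffixes(self, table: list[tuple[str, str]]) -> None:
        for suffix, repl in table:
            if self._ends(suffix):
                self._r(repl)
                return

    _STEP4 = [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ]

    def _step4(self) -> None:
        for suffix in self._STEP4:
            if self._ends(suffix):
                if suffix == "ion" and (self.j < 0 or self.b[self.j] not in "st"):
                    continue
                if self._m() > 1:
                    self.k = self.j
                return

    def _step5(self) -> None:
        self.j = self.k
        if self.b[self.k] == "e":
            m = self._m()
            if m > 1 or (m == 1 and not self._cvc(self.k - 1)):
                self.k -= 1
        if self.b[self.k] == "l" and self._double_c(self.k) and self._m() > 1:
            self.k -= 1

    def run(self) -> str:
        if self.k <= 1:
            return self.b
        self._step1ab()
        self._step1c()
        self._map_suffixes(self._STEP2)
        self._map_suffixes(self._STEP3)
        self._step4()
        self._step5()
        return self.b[: self.k + 1]


def porter_stem(word: str) -> str:
    """Stem a single lowercase word."""
    return _Stemmer(word).run()
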