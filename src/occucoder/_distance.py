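"""Damerau-Levenshtein edit distance (restricted / optimal string alignment).

Counts single-character substitutions, insertions, deletions and adjacent
transpositions, each at unit cost.  The restricted variant is used: a
transposed pair may not be edited further, which is the convention of most
spell-checking literature and is exact for the single-typo corrections this
package performs.
"""

from __future__ import annotations


def damerau_levenshtein(a: str, b: str, max_distance: int | None = None) -> int:
    """Edit distance between ``a`` and ``b``.

    Parameters
    ----------
    a, b:
        The two strings to compare.
    max_distance:
        Optional early-exit bound: when every alignment already exceeds it,
        ``max_distance + 1`` is returned.  Useful when only "within k edits"
        matters, as in vocabulary lookup.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    if max_distance is not None and abs(la - lb) > max_distance:
        return max_distance + 1

    # three rolling rows of the OSA dynamic programme
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1,        # deletion
                         cur[j - 1] + 1,     # insertion
                         prev[j - 1] + cost)  # substitution / match
            if (i > 1 and j > 1
                    and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]):
                cur[j] = min(cur[j], prev2[j - 2] + 1)  # transposition
        if max_distance is not None and min(cur) > max_distance:
            return max_distance + 1
        prev2, prev = prev, cur
    return prev[lb]


def within_distance(a: str, b: str, k: int) -> bool:
    """True iff ``damerau_levenshtein(a, b) <= k``."""
    return damerau_levenshtein(a, b, max_distance=k) <= k
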