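"""Digit-level agreement, production rate, accuracy and transition matrices.

Automated occupation coding is scored against manual (gold) codes at each
digit of the hierarchical code: the *match level* of two 4-digit codes is
the length of their longest common digit prefix, so 2225 vs 2215 is a
two-digit match (same broad category and major group, different minor
group).  The *production rate* is the fraction of records assigned any
code at all; *k-digit accuracy* is the fraction of ALL records (unassigned
ones count as level 0) whose assigned code agrees with the gold code to at
least k digits -- which makes accuracy monotonically non-increasing in k
by construction.

Two algorithm variants are compared by a 5x5 *transition matrix* of match
levels (none/1/2/3/4), diagonal excluded: rows index the earlier variant,
columns the later one, so the column sums above a level give the records
gained at that level and the row sums the records lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .noc import NocError

LEVELS = (0, 1, 2, 3, 4)  # 0 = no match / unassigned


def digit_match_level(a: str, b: str) -> int:
    """Length of the longest common digit prefix of two 4-digit codes.

    >>> digit_match_level("2225", "2215")
    2
    """
    for code in (a, b):
        if not isinstance(code, str) or len(code) != 4 or not code.isdigit():
            raise NocError(f"digit_match_level needs 4-digit codes, got {code!r}")
    level = 0
    for x, y in zip(a, b):
        if x != y:
            break
        level += 1
    return level


@dataclass(frozen=True)
class EvalSummary:
    """Aggregate performance of one coded batch against gold codes."""

    n_records: int
    n_coded: int
    production_rate: float
    accuracy_at: dict[int, float]  # digit level 1-4 -> fraction of all records


def result_levels(results: Iterable) -> list[int]:
    """Match level of each coded result vs its gold code (0 if unassigned)."""
    levels = []
    for r in results:
        if r.input.gold_code is None:
            raise NocError("every result needs a gold code for evaluation")
        if r.assigned is None:
            levels.append(0)
        else:
            levels.append(digit_match_level(r.assigned, r.input.gold_code))
    return levels


def evaluate(results: Sequence) -> EvalSummary:
    """Production rate and per-digit accuracy over coded results.

    The accuracy denominator is all records, not only the coded ones:
    uncoded records simply cannot agree at any digit.
    """
    if not results:
        raise NocError("no results to evaluate")
    levels = result_levels(results)
    n = len(results)
    n_coded = sum(1 for r in results if r.assigned is not None)
    accuracy = {k: sum(1 for lv in levels if lv >= k) / n for k in (1, 2, 3, 4)}
    return EvalSummary(n_records=n, n_coded=n_coded,
                       production_rate=n_coded / n, accuracy_at=accuracy)


@dataclass(frozen=True)
class TransitionMatrix:
    """5x5 cross-tab of match levels between two algorithm variants.

    ``counts[i, j]`` is the number of records at level ``i`` under the
    earlier variant and level ``j`` under the later one; the diagonal
    (records whose level did not change) is zero by convention.
    """

    counts: np.ndarray  # shape (5, 5), dtype int

    def __post_init__(self) -> None:
        if self.counts.shape != (5, 5):
            raise NocError("transition matrix must be 5x5")

    @classmethod
    def from_cells(cls, cells: dict[tuple[int, int], int]) -> "TransitionMatrix":
        counts = np.zeros((5, 5), dtype=int)
        for (i, j), v in cells.items():
            if i == j:
                raise NocError("diagonal cells are undefined by convention")
            counts[i, j] = v
        return cls(counts)

    def gains(self, level: int) -> int:
        """Records that reached ``level`` under the later variant."""
        return int(self.counts[:, level].sum())

    def losses(self, level: int) -> int:
        """Records that left ``level`` between the variants."""
        return int(self.counts[level, :].sum())

    def net(self, level: int) -> int:
        return self.gains(level) - self.losses(level)

    @property
    def total_changed(self) -> int:
        return int(self.counts.sum())


def transition_matrix(levels_earlier: Sequence[int | None],
                      levels_later: Sequence[int | None]) -> TransitionMatrix:
    """Cross-tabulate per-record match levels of two variants.

    ``None`` (no match) is folded into level 0.  Records whose level did
    not change are not counted, matching the diagonal-undefined
    convention of the printed comparison tables.
    """
    if len(levels_earlier) != len(levels_later):
        raise NocError("level lists must have equal length")
    counts = np.zeros((5, 5), dtype=int)
    for a, b in zip(levels_earlier, levels_later):
        i = 0 if a is None else int(a)
        j = 0 if b is None else int(b)
        if not (0 <= i <= 4 and 0 <= j <= 4):
            raise NocError(f"match levels must be 0-4, got {a!r}, {b!r}")
        if i != j:
            counts[i, j] += 1
    return TransitionMatrix(counts)


def summary_row(summary: EvalSummary) -> dict[str, float]:
    """One flat row of percentages, shaped like the published benchmark table."""
    return {
        "production_rate_pct": round(100 * summary.production_rate, 1),
        "accuracy_1digit_pct": round(100 * summary.accuracy_at[1], 1),
        "accuracy_2digit_pct": round(100 * summary.accuracy_at[2], 1),
        "accuracy_3digit_pct": round(100 * summary.accuracy_at[3], 1),
        "accuracy_4digit_pct": round(100 * summary.accuracy_at[4], 1),
    }
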