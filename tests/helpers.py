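"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: alignment scores come
from exhaustive recursion over alignment paths, mosaic costs from
enumeration of all 2^n parent assignments, and stretches from a per-column
scan.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

GAP = "-"


def brute_force_align_score(a: str, b: str, match, mismatch, gap_open, gap_extend) -> float:
    """Optimal global affine-gap score by exhaustive recursion.

    Convention: the first column of a gap scores gap_open, each further
    column gap_extend. Intended for lengths <= 6.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            g = gap_extend if prev == "X" else gap_open
            best = max(best, g + rec(i + 1, j, "X"))
        if j < len(b):  # gap in a
            g = gap_extend if prev == "Y" else gap_open
            best = max(best, g + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "M")


def brute_force_mosaic_cost(states: list[str], switch_cost: float, mismatch_cost: float):
    """Minimum assignment cost over all 2^n labelings.

    ``states`` entries are "A", "B" or "N" (matches neither). Returns
    (min_cost, min_switches_at_min_cost).
    """
    n = len(states)
    best = (float("inf"), n + 1)
    for labels in itertools.product("AB", repeat=n):
        switches = sum(1 for x, y in zip(labels, labels[1:]) if x != y)
        mism = sum(1 for s, l in zip(states, labels) if s != l)
        cost = switch_cost * switches + mismatch_cost * mism
        best = min(best, (cost, switches))
    return best


def brute_force_stretches(row_a: str, row_b: str) -> list[tuple[int, int]]:
    """Maximal identical gap-free column runs as (start, end) inclusive."""
    ident = [
        a == b and a != GAP and b != GAP for a, b in zip(row_a, row_b)
    ]
    out = []
    i = 0
    while i < len(ident):
        if ident[i]:
            j = i
            while j + 1 < len(ident) and ident[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def random_gapped_pair(rng, length: int = 40) -> tuple[str, str]:
    """A random pair of aligned rows with gaps but no all-gap column."""
    rows = [[], []]
    for _ in range(length):
        kind = rng.integers(4)
        ca = rng.choice(list("ACGT"))
        cb = rng.choice(list("ACGT"))
        if kind == 0:
            rows[0].append(ca)
            rows[1].append(GAP)
        elif kind == 1:
            rows[0].append(GAP)
            rows[1].append(cb)
        elif kind == 2:
            rows[0].append(ca)
            rows[1].append(ca)
        else:
            rows[0].append(ca)
            rows[1].append(cb)
    return "".join(rows[0]), "".join(rows[1])
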