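"""Maximal identical gap-free stretches between two parent sequences.

A crossover by homologous recombination requires a tract of contiguous
identity between the recombining molecules, so the stretch spanning a
breakpoint's ambiguity interval is the homology that enabled it. Stretches
are enumerated on alignment columns; gaps terminate a stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .seqcore import GAP, PairwiseAlignment, TripleAlignment
from .mosaic import BreakpointInterval


@dataclass(frozen=True)
class SharedStretch:
    """Maximal run of identical gap-free columns between the two parents.

    ``start_col``/``end_col`` are inclusive alignment columns; ``start_a`` ..
    ``end_b`` are the corresponding 1-based inclusive coordinates on each
    parent's ungapped sequence. A zero-length sentinel (``length == 0``)
    flags a breakpoint whose flanking discriminating sites are adjacent.
    """

    start_col: int
    end_col: int
    length: int
    start_a: int = 0
    end_a: int = 0
    start_b: int = 0
    end_b: int = 0
    contains_breakpoint: bool = False

    @property
    def is_sentinel(self) -> bool:
        return self.length == 0


def _parent_rows(aln) -> tuple[str, str]:
    if isinstance(aln, TripleAlignment):
        return aln.rows[1], aln.rows[2]
    if isinstance(aln, PairwiseAlignment):
        return aln.rows
    a, b = aln
    return a, b


def shared_stretches(aln) -> list[SharedStretch]:
    """Maximal identical gap-free runs between the parents, sorted by start.

    Accepts a TripleAlignment (parents are rows 1 and 2), a
    PairwiseAlignment of the two parents, or a plain (row_a, row_b) pair of
    gapped strings.
    """
    row_a, row_b = _parent_rows(aln)
    if len(row_a) != len(row_b):
        raise ValueError("parent rows differ in length")
    out: list[SharedStretch] = []
    pos_a = pos_b = 0  # 0-based ungapped positions consumed so far
    run_start = None
    run_a = run_b = 0
    for col in range(len(row_a) + 1):
        ident = False
        if col < len(row_a):
            ca, cb = row_a[col], row_b[col]
            ident = ca != GAP and cb != GAP and ca == cb
        if ident and run_start is None:
            run_start, run_a, run_b = col, pos_a, pos_b
        if not ident and run_start is not None:
            out.append(
                SharedStretch(
                    start_col=run_start,
                    end_col=col - 1,
                    length=col - run_start,
                    start_a=run_a + 1,
                    end_a=pos_a,
                    start_b=run_b + 1,
                    end_b=pos_b,
                )
            )
            run_start = None
        if col < len(row_a):
            if row_a[col] != GAP:
                pos_a += 1
            if row_b[col] != GAP:
                pos_b += 1
    return out


def stretch_at_breakpoint(
    bp: BreakpointInterval, stretches: list[SharedStretch]
) -> SharedStretch:
    """The homology tract in which the crossover behind `bp` occurred.

    Returns the stretch lying strictly between the breakpoint's flanking
    discriminating sites, flagged with ``contains_breakpoint=True``. If gaps
    split the interval into several stretches the longest is returned (the
    crossover is unidentifiable among them; the longest is the maximal
    homology available). Adjacent flanking sites with no identical column in
    between yield a zero-length sentinel.
    """
    inside = [s for s in stretches if bp.left < s.start_col and s.end_col < bp.right]
    if not inside:
        return SharedStretch(
            start_col=bp.right, end_col=bp.left, length=0, contains_breakpoint=True
        )
    best = max(inside, key=lambda s: (s.length, -s.start_col))
    return replace(best, contains_breakpoint=True)


def stretch_length_distribution(stretches: list[SharedStretch]) -> pd.DataFrame:
    """Histogram of stretch lengths with a cumulative "fraction >= k" column.

    Returns a DataFrame with columns ``length``, ``count``,
    ``cumulative_fraction`` where ``cumulative_fraction`` at length k is the
    fraction of stretches of length >= k.
    """
    if not stretches:
        raise ValueError("empty stretch list")
    counts = pd.Series([s.length for s in stretches]).value_counts().sort_index()
    total = int(counts.sum())
    cum_ge = counts[::-1].cumsum()[::-1] / total
    return pd.DataFrame(
        {
            "length": counts.index.to_numpy(),
            "count": counts.to_numpy(),
            "cumulative_fraction": cum_ge.to_numpy(),
        }
    )
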