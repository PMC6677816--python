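"""Sequence I/O, pairwise global alignment and three-way alignment construction.

Nucleotide sequences are normalized to DNA on input (U -> T); all internal
coordinates are 0-based half-open, all user-facing coordinates 1-based
inclusive, matching the usual genomic-locus convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import Align

GAP = "-"
_ALLOWED = set("ACGTN")


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, stored as DNA (U normalized to T)."""

    id: str
    residues: str
    description: str = ""
    was_rna: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains disallowed symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def as_input_alphabet(self) -> str:
        """Residues in the original alphabet (RNA restored if input was RNA)."""
        return self.residues.replace("T", "U") if self.was_rna else self.residues


def _normalize(raw: str, record_id: str, line_no: int) -> tuple[str, bool]:
    seq = raw.upper()
    was_rna = "U" in seq
    seq = seq.replace("U", "T")
    bad = set(seq) - _ALLOWED
    if bad:
        raise FastaParseError(
            f"line {line_no}: disallowed residue(s) {sorted(bad)} in record {record_id!r}"
        )
    return seq, was_rna


def read_fasta(path: str | os.PathLike, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Parameters
    ----------
    path
        FASTA file. RNA (U) is accepted and normalized to T.
    allow_gaps
        Accept ``-`` characters (aligned FASTA). Gap-containing records are
        returned with gaps intact in ``residues``.

    Raises
    ------
    FastaParseError
        On a malformed header, a disallowed residue, or a duplicate id; the
        message names the line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []
    first_line: int | None = None

    def flush(line_no: int):
        nonlocal cur_id
        if cur_id is None:
            return
        raw = "".join(chunks)
        if allow_gaps:
            raw_nogap = raw.replace(GAP, "")
        else:
            raw_nogap = raw
        seq, was_rna = _normalize(raw_nogap, cur_id, first_line or line_no)
        if allow_gaps and GAP in raw:
            seq = raw.upper().replace("U", "T")
        if not seq:
            raise FastaParseError(f"line {first_line}: record {cur_id!r} has no residues")
        if cur_id in seen:
            raise FastaParseError(f"line {first_line}: duplicate id {cur_id!r}")
        seen.add(cur_id)
        rec = object.__new__(SequenceRecord)
        object.__setattr__(rec, "id", cur_id)
        object.__setattr__(rec, "residues", seq)
        object.__setattr__(rec, "description", cur_desc)
        object.__setattr__(rec, "was_rna", was_rna)
        if GAP not in seq:
            # route through the validating constructor for ungapped records
            rec = SequenceRecord(cur_id, seq, cur_desc, was_rna)
        records.append(rec)
        cur_id = None

    i = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"line {i}: empty FASTA header")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                first_line = i + 1
            else:
                if cur_id is None:
                    raise FastaParseError(f"line {i}: sequence data before any header")
                chunks.append(line.strip())
        flush(i)
    return records


def write_fasta(records, path: str | os.PathLike, width: int = 70) -> None:
    """Write records (SequenceRecord or (id, seq) pairs) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, SequenceRecord):
                rid, seq, desc = rec.id, rec.residues, rec.description
            else:
                rid, seq = rec
                desc = ""
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring. A gap of length k scores gap_open + (k-1)*gap_extend."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length plus the alignment score."""

    rows: tuple[str, str]
    score: float
    params: AlignParams

    def __post_init__(self):
        a, b = self.rows
        if len(a) != len(b):
            raise ValueError("alignment rows differ in length")
        for col in range(len(a)):
            if a[col] == GAP and b[col] == GAP:
                raise ValueError(f"all-gap column at {col}")

    def __len__(self) -> int:
        return len(self.rows[0])

    def degapped(self, row: int) -> str:
        return self.rows[row].replace(GAP, "")


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    params: AlignParams | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring.

    Deterministic: among co-optimal alignments the aligner's first traceback
    is returned (fixed tie-break order), so identical inputs always give
    identical output.
    """
    params = params or AlignParams()
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params)
    aln = aligner.align(sa, sb)[0]
    return PairwiseAlignment(rows=(str(aln[0]), str(aln[1])), score=aln.score, params=params)


def percent_identity(aln: PairwiseAlignment, convention: str = "trim_ends") -> float:
    """Percent identical columns of a pairwise alignment.

    convention
        ``trim_ends`` (default): denominator excludes terminal-gap overhang
        columns; ``all_columns``: every column counts; ``ungapped``: gap-free
        columns only. Identity numerator is always the identical residue
        columns.
    """
    a, b = aln.rows
    n = len(a)
    lo, hi = 0, n
    if convention == "trim_ends":
        while lo < n and (a[lo] == GAP or b[lo] == GAP):
            lo += 1
        while hi > lo and (a[hi - 1] == GAP or b[hi - 1] == GAP):
            hi -= 1
    elif convention not in ("all_columns", "ungapped"):
        raise ValueError(f"unknown identity convention {convention!r}")

    ident = 0
    denom = 0
    for i in range(lo, hi):
        ca, cb = a[i], b[i]
        if convention == "ungapped" and (ca == GAP or cb == GAP):
            continue
        denom += 1
        if ca == cb and ca != GAP:
            ident += 1
    if denom == 0:
        raise ValueError("identity denominator is zero under this convention")
    return 100.0 * ident / denom


class TripleAlignment:
    """Recombinant + two parents in common columns, merged on the recombinant.

    Row order: 0 = recombinant, 1 = parent A (host), 2 = parent B (donor).
    The recombinant row is gap-free except at columns carrying a parent
    insertion relative to it.
    """

    def __init__(self, rows: tuple[str, str, str]):
        r, a, b = rows
        if not (len(r) == len(a) == len(b)):
            raise ValueError("rows differ in length")
        for col in range(len(r)):
            if r[col] == GAP and a[col] == GAP and b[col] == GAP:
                raise ValueError(f"all-gap column at {col}")
        self.rows = (r, a, b)
        # per-row maps: ungapped position -> column, and column -> position
        self._pos2col: list[list[int]] = []
        self._col2pos: list[list[int | None]] = []
        for row in self.rows:
            p2c, c2p = [], []
            pos = 0
            for col, ch in enumerate(row):
                if ch == GAP:
                    c2p.append(None)
                else:
                    p2c.append(col)
                    c2p.append(pos)
                    pos += 1
            self._pos2col.append(p2c)
            self._col2pos.append(c2p)

    def __len__(self) -> int:
        return len(self.rows[0])

    def degapped(self, row: int) -> str:
        return self.rows[row].replace(GAP, "")

    def col_of(self, row: int, pos: int) -> int:
        """Alignment column of 0-based ungapped position `pos` in `row`."""
        return self._pos2col[row][pos]

    def pos_of(self, row: int, col: int) -> int | None:
        """0-based ungapped position of `row` at `col`, or None at a gap."""
        return self._col2pos[row][col]

    def n_gapped_columns(self) -> int:
        return sum(
            1
            for col in range(len(self))
            if any(row[col] == GAP for row in self.rows)
        )


def _parent_onto_focal(focal: str, parent: str, params: AlignParams):
    """Align parent to focal; return (per-position parent chars, insertions).

    ``chars[i]`` is the parent residue (or gap) aligned to focal position i;
    ``inserts[i]`` is the parent sequence inserted immediately before focal
    position i (index len(focal) = trailing insertion).
    """
    aln = global_align(focal, parent, params)
    frow, prow = aln.rows
    chars: list[str] = []
    inserts: list[str] = ["" for _ in range(len(focal) + 1)]
    fpos = 0
    for col in range(len(frow)):
        if frow[col] == GAP:
            inserts[fpos] += prow[col]
        else:
            chars.append(prow[col])
            fpos += 1
    return chars, inserts


def align_triple(
    recombinant: SequenceRecord | str,
    parent_a: SequenceRecord | str,
    parent_b: SequenceRecord | str,
    params: AlignParams | None = None,
) -> TripleAlignment:
    """Merge two recombinant-anchored global alignments into three rows.

    Each parent is globally aligned to the recombinant; columns are merged on
    recombinant coordinates. Parent insertions are emitted as their own
    columns (A's before B's at the same junction) and are not aligned to each
    other.
    """
    params = params or AlignParams()
    r = recombinant.residues if isinstance(recombinant, SequenceRecord) else recombinant
    chars_a, ins_a = _parent_onto_focal(r, parent_a.residues if isinstance(parent_a, SequenceRecord) else parent_a, params)
    chars_b, ins_b = _parent_onto_focal(r, parent_b.residues if isinstance(parent_b, SequenceRecord) else parent_b, params)

    out_r, out_a, out_b = [], [], []
    for i in range(len(r) + 1):
        for ch in ins_a[i]:
            out_r.append(GAP)
            out_a.append(ch)
            out_b.append(GAP)
        for ch in ins_b[i]:
            out_r.append(GAP)
            out_a.append(GAP)
            out_b.append(ch)
        if i < len(r):
            out_r.append(r[i])
            out_a.append(chars_a[i])
            out_b.append(chars_b[i])
    return TripleAlignment(("".join(out_r), "".join(out_a), "".join(out_b)))
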