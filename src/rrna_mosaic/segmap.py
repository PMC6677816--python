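"""Mapping boundary positions onto an accretion-segment / helix annotation.

The annotation assigns reference-coordinate ranges to structural segments of
the 16S rRNA ranked by their inferred order of addition during early
ribosomal evolution (lower ``age_rank`` = older). Boundary positions inferred
on a recombinant are first transferred to the reference coordinate system via
a pairwise alignment, then counted per segment.

Annotation files are tab-delimited with a header
``segment_id  age_rank  start  end  kind  label`` (1-based inclusive
coordinates) or BED (0-based half-open; auto-detected by a ``.bed``
extension). The segment ranges themselves are user-supplied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .seqcore import GAP, PairwiseAlignment

KINDS = ("accretion_segment", "helix")


@dataclass(frozen=True)
class SegmentRecord:
    segment_id: str
    age_rank: int
    start: int  # 1-based inclusive
    end: int
    kind: str = "accretion_segment"
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.segment_id}: start > end")
        if self.kind not in KINDS:
            raise ValueError(f"{self.segment_id}: unknown kind {self.kind!r}")
        if self.age_rank < 1:
            raise ValueError(f"{self.segment_id}: age_rank must be >= 1")


@dataclass
class SegmentAnnotation:
    records: list[SegmentRecord]
    reference_id: str = "reference"

    def __post_init__(self):
        for kind in KINDS:
            recs = sorted(
                (r for r in self.records if r.kind == kind), key=lambda r: r.start
            )
            for u, v in zip(recs, recs[1:]):
                if v.start <= u.end:
                    raise ValueError(
                        f"overlapping {kind} records {u.segment_id!r} and {v.segment_id!r}"
                    )
        ranks = [r.age_rank for r in self.records if r.kind == "accretion_segment"]
        if len(ranks) != len(set(ranks)):
            raise ValueError("duplicate age_rank among accretion segments")

    def segments(self, kind: str = "accretion_segment") -> list[SegmentRecord]:
        return sorted((r for r in self.records if r.kind == kind), key=lambda r: r.start)


_COLUMNS = ["segment_id", "age_rank", "start", "end", "kind", "label"]


def load_annotation(path: str | os.PathLike, reference_id: str = "reference") -> SegmentAnnotation:
    """Load a TSV (1-based inclusive) or BED (0-based half-open) annotation."""
    path = os.fspath(path)
    if path.endswith(".bed"):
        return _load_bed(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            records.append(
                SegmentRecord(
                    segment_id=row["segment_id"],
                    age_rank=int(row["age_rank"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    kind=row["kind"],
                    label=row.get("label", ""),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return SegmentAnnotation(records, reference_id=reference_id)


def _load_bed(path: str) -> SegmentAnnotation:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str, keep_default_na=False
    )
    records = []
    ref_id = "reference"
    for i, row in df.iterrows():
        try:
            ref_id = row[0]
            start0, end0 = int(row[1]), int(row[2])
            name = row[3] if len(row) > 3 else f"seg{i + 1}"
            rank = int(row[4]) if len(row) > 4 and row[4] not in (".", "") else i + 1
            records.append(
                SegmentRecord(name, rank, start0 + 1, end0, "accretion_segment")
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{path} line {i + 1}: {exc}") from exc
    return SegmentAnnotation(records, reference_id=str(ref_id))


def write_annotation(ann: SegmentAnnotation, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (r.segment_id, r.age_rank, r.start, r.end, r.kind, r.label)
            for r in ann.records
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def transfer_to_reference(
    pos: int, aln: PairwiseAlignment
) -> tuple[int, bool]:
    """Transfer a 1-based recombinant position to reference coordinates.

    ``aln`` aligns the recombinant (row 0) to the reference (row 1). Returns
    ``(reference_position, exact)``; if the reference is gapped at the
    matched column the nearest 5' reference position is returned with
    ``exact=False``. Position 0 is returned (inexact) for a 5'-terminal gap.
    """
    rec_row, ref_row = aln.rows
    rec_len = len(rec_row) - rec_row.count(GAP)
    if not 1 <= pos <= rec_len:
        raise ValueError(f"position {pos} outside recombinant length {rec_len}")
    rec_pos = 0
    ref_pos = 0
    for col in range(len(rec_row)):
        if ref_row[col] != GAP:
            ref_pos += 1
        if rec_row[col] != GAP:
            rec_pos += 1
            if rec_pos == pos:
                if ref_row[col] == GAP:
                    return ref_pos, False
                return ref_pos, True
    raise AssertionError("unreachable")


def map_boundaries(
    points: list[int], ann: SegmentAnnotation, kind: str = "accretion_segment"
) -> tuple[pd.DataFrame, int]:
    """Count boundary points per annotated segment.

    Returns a DataFrame (``segment_id``, ``age_rank``, ``start``, ``end``,
    ``count``) sorted by age_rank, plus the number of points falling in no
    segment. Counts plus unassigned always sum to ``len(points)``; a point on
    a segment edge belongs to the segment containing that exact position.
    """
    segs = ann.segments(kind)
    counts = {s.segment_id: 0 for s in segs}
    unassigned = 0
    for p in points:
        hit = next((s for s in segs if s.start <= p <= s.end), None)
        if hit is None:
            unassigned += 1
        else:
            counts[hit.segment_id] += 1
    df = pd.DataFrame(
        [(s.segment_id, s.age_rank, s.start, s.end, counts[s.segment_id]) for s in segs],
        columns=["segment_id", "age_rank", "start", "end", "count"],
    ).sort_values("age_rank", ignore_index=True)
    return df, unassigned


def oldest_fraction(
    counts: pd.DataFrame, k: int, n_unassigned: int = 0
) -> tuple[int, int, float]:
    """Boundary share of the k oldest segments.

    Returns ``(count_in_k_oldest, total, fraction)`` where total includes
    unassigned points. Non-decreasing in k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = int(counts["count"].sum()) + n_unassigned
    if total == 0:
        raise ValueError("no boundary points to summarize")
    in_k = int(counts.loc[counts["age_rank"] <= k, "count"].sum())
    return in_k, total, in_k / total
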