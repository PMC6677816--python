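"""Column-class composition statistics across aligned homologs.

Columns of a multiple alignment are classed as gapped, consensus (all rows
identical) or discriminating (some rows differ). The GC content of each
sequence is then computed separately over its discriminating and consensus
columns: in thermophilic rRNAs the variable (species-specific) positions are
markedly GC-enriched relative to the conserved core, a signature of thermal
adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import GAP, SequenceRecord

GC = frozenset("GC")


@dataclass
class ColumnClassProfile:
    """Column classes of an MSA plus per-sequence GC% by class.

    ``per_sequence_gc`` maps sequence id -> (gc_discriminating, gc_consensus)
    in percent; a class with zero columns is reported as None (undefined),
    never 0.
    """

    n_consensus: int
    n_discriminating: int
    n_gapped: int
    column_classes: list[str] = field(repr=False)  # per column: "consensus"|"discriminating"|"gapped"
    per_sequence_gc: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )

    @property
    def n_columns(self) -> int:
        return self.n_consensus + self.n_discriminating + self.n_gapped


def _rows(msa) -> tuple[list[str], list[str]]:
    ids, rows = [], []
    for i, rec in enumerate(msa):
        if isinstance(rec, SequenceRecord):
            ids.append(rec.id)
            rows.append(rec.residues)
        else:
            ids.append(f"seq{i + 1}")
            rows.append(rec)
    if len(rows) < 2:
        raise ValueError("need at least two sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    return ids, rows


def classify_msa_columns(
    msa, mode: str = "unanimous", focal_id: str | None = None
) -> ColumnClassProfile:
    """Classify every column of an aligned set of >= 2 sequences.

    mode
        ``unanimous`` (default): a gap-free column is consensus iff all rows
        carry the same residue. ``focal``: consensus iff all rows agree with
        the focal sequence (``focal_id``, default the first row) — a
        pairwise-vs-focal alternative; with the full set compared this
        coincides with ``unanimous``.
    """
    ids, rows = _rows(msa)
    if mode == "focal":
        focal = rows[ids.index(focal_id)] if focal_id is not None else rows[0]
    elif mode != "unanimous":
        raise ValueError(f"unknown mode {mode!r}")
    classes = []
    for col in range(len(rows[0])):
        col_chars = [r[col] for r in rows]
        if GAP in col_chars:
            classes.append("gapped")
        elif mode == "focal":
            classes.append(
                "consensus" if all(c == focal[col] for c in col_chars) else "discriminating"
            )
        else:
            classes.append("consensus" if len(set(col_chars)) == 1 else "discriminating")
    return ColumnClassProfile(
        n_consensus=classes.count("consensus"),
        n_discriminating=classes.count("discriminating"),
        n_gapped=classes.count("gapped"),
        column_classes=classes,
    )


def _gc_percent(chars: list[str]) -> float | None:
    if not chars:
        return None
    return 100.0 * sum(1 for c in chars if c in GC) / len(chars)


def gc_by_class(msa, profile: ColumnClassProfile) -> ColumnClassProfile:
    """Fill in per-sequence GC% over discriminating and consensus columns."""
    ids, rows = _rows(msa)
    if len(rows[0]) != len(profile.column_classes):
        raise ValueError("profile does not match this alignment")
    for sid, row in zip(ids, rows):
        disc = [row[c] for c, k in enumerate(profile.column_classes) if k == "discriminating"]
        cons = [row[c] for c, k in enumerate(profile.column_classes) if k == "consensus"]
        profile.per_sequence_gc[sid] = (_gc_percent(disc), _gc_percent(cons))
    return profile
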