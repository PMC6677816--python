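"""High-level convenience: full chimera analysis of one recombinant."""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import AlignParams, SequenceRecord, TripleAlignment, align_triple
from .mosaic import (
    DiscriminatingSite,
    MosaicPath,
    boundary_points,
    call_chimera_class,
    find_discriminating_sites,
    infer_mosaic,
)
from .stretches import SharedStretch, shared_stretches, stretch_at_breakpoint


@dataclass
class ChimeraAnalysis:
    """Everything inferred about one recombinant vs its two parents."""

    alignment: TripleAlignment
    sites: list[DiscriminatingSite]
    path: MosaicPath | None  # None when there are no discriminating sites
    boundary_positions: list[int]  # recombinant 1-based
    intervals: list[tuple[int, int]]  # recombinant 1-based (left, right]
    homology_tracts: list[SharedStretch]  # one per breakpoint
    outcome_class: str


def analyze_recombinant(
    recombinant: SequenceRecord | str,
    host: SequenceRecord | str,
    donor: SequenceRecord | str,
    switch_cost: float = 2.0,
    mismatch_cost: float = 1.0,
    params: AlignParams | None = None,
) -> ChimeraAnalysis:
    """Align, call sites, infer the mosaic and attribute homology tracts.

    The host is parent A; ``outcome_class`` is ``intact`` when the
    recombinant carries no donor-matching site (including the no-site case).
    """
    aln = align_triple(recombinant, host, donor, params)
    sites = find_discriminating_sites(aln)
    if not sites:
        return ChimeraAnalysis(aln, [], None, [], [], [], "intact")
    path = infer_mosaic(sites, switch_cost, mismatch_cost)
    points = boundary_points(path, aln)
    stretches = shared_stretches(aln)
    intervals = []
    tracts = []
    for bp in path.breakpoints:
        left = aln.pos_of(0, bp.left)
        right = aln.pos_of(0, bp.right)
        assert left is not None and right is not None
        intervals.append((left + 1, right + 1))
        tracts.append(stretch_at_breakpoint(bp, stretches))
    return ChimeraAnalysis(
        aln, sites, path, points, intervals, tracts, call_chimera_class(path, sites)
    )
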