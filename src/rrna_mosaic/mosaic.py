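"""Minimal-crossover parent-of-origin inference for a recombinant gene.

Given a three-way alignment (recombinant, host parent A, donor parent B), the
columns at which the two parents differ — the discriminating sites — are the
only positions carrying information about parental origin. A mosaic is an
assignment of each site to one parent; we seek the assignment minimizing

    switch_cost * (#label changes) + mismatch_cost * (#contradicted sites)

by dynamic programming over sites x {A, B}. A site whose recombinant base
matches neither parent (a candidate de novo mutation) contradicts both labels
equally. The true crossover behind each label change is unidentifiable within
the flanked identity tract, so each breakpoint is reported both as the field's
point convention — the first discriminating nucleotide attributable to the new
parent — and as the ambiguity interval between the flanking sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .seqcore import GAP, TripleAlignment


class SiteState(Enum):
    MATCHES_A = "matches_A"
    MATCHES_B = "matches_B"
    MATCHES_NEITHER = "matches_neither"


@dataclass(frozen=True)
class DiscriminatingSite:
    """A gap-free alignment column at which the two parents differ."""

    column: int  # 0-based alignment column
    parent_a_base: str
    parent_b_base: str
    state: SiteState

    def __post_init__(self):
        if self.parent_a_base == self.parent_b_base:
            raise ValueError("parents agree at a discriminating site")


@dataclass(frozen=True)
class BreakpointInterval:
    """Ambiguity interval of one crossover.

    ``left``/``right`` are alignment columns of the last site assigned to the
    preceding parent and the first site assigned to the following parent.
    ``boundary_point`` is the point convention: the first discriminating
    nucleotide of the new parent, i.e. ``right``.
    """

    left: int
    right: int
    reference_position: int | None = None

    def __post_init__(self):
        if not self.left < self.right:
            raise ValueError("breakpoint interval requires left < right")

    @property
    def boundary_point(self) -> int:
        return self.right


@dataclass(frozen=True)
class MosaicSegment:
    parent: str  # "A" or "B"
    first_site: int  # index into the site list
    last_site: int


@dataclass
class MosaicPath:
    """Optimal mosaic: segments, breakpoints and the DP objective value."""

    segments: list[MosaicSegment]
    breakpoints: list[BreakpointInterval]
    n_mismatch: int  # sites whose state contradicts their assigned label
    cost: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        for s, t in zip(self.segments, self.segments[1:]):
            if s.parent == t.parent:
                raise ValueError("adjacent segments share a parent label")
        if len(self.breakpoints) != len(self.segments) - 1:
            raise ValueError("breakpoint count must be segment count - 1")

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)


def find_discriminating_sites(aln: TripleAlignment) -> list[DiscriminatingSite]:
    """All gap-free columns where the parents differ, in column order.

    Columns with a gap in any of the three rows are excluded (indel
    differences contribute to identity but not to boundary calling); their
    count is available from ``aln.n_gapped_columns()``.
    """
    rec, pa, pb = aln.rows
    sites = []
    for col in range(len(aln)):
        r, a, b = rec[col], pa[col], pb[col]
        if GAP in (r, a, b) or a == b:
            continue
        if r == a:
            state = SiteState.MATCHES_A
        elif r == b:
            state = SiteState.MATCHES_B
        else:
            state = SiteState.MATCHES_NEITHER
        sites.append(DiscriminatingSite(col, a, b, state))
    return sites


def _site_penalty(state: SiteState, label: str, mismatch_cost: float) -> float:
    if state is SiteState.MATCHES_NEITHER:
        return mismatch_cost
    matches = SiteState.MATCHES_A if label == "A" else SiteState.MATCHES_B
    return 0.0 if state is matches else mismatch_cost


def infer_mosaic(
    sites: list[DiscriminatingSite],
    switch_cost: float = 2.0,
    mismatch_cost: float = 1.0,
) -> MosaicPath:
    """Minimal-cost parent assignment of the discriminating sites.

    Dynamic programming over sites x {A, B}; O(n) time. Ties are broken
    deterministically: fewer segments first, then the first segment assigned
    to the host parent A.

    Raises
    ------
    ValueError
        If the site list is empty — the recombinant is indistinguishable
        from either parent and has no mosaic structure to infer.
    """
    if not sites:
        raise ValueError(
            "no discriminating sites: the parents are identical at every "
            "aligned column, so the recombinant cannot be attributed"
        )
    if switch_cost <= 0 or mismatch_cost <= 0:
        raise ValueError("costs must be positive")

    n = len(sites)
    labels = ("A", "B")
    # backward DP on (cost, n_switches); best[i][l] = best labeling of sites i..n-1
    # given site i carries label l.
    INF = (float("inf"), 0)
    best = [[INF, INF] for _ in range(n + 1)]
    best[n][0] = best[n][1] = (0.0, 0)
    choice = [[0, 0] for _ in range(n)]  # preferred next label index
    for i in range(n - 1, -1, -1):
        for li, lab in enumerate(labels):
            pen = _site_penalty(sites[i].state, lab, mismatch_cost)
            if i == n - 1:
                best[i][li] = (pen, 0)
                continue
            cands = []
            for lj in range(2):
                c, sw = best[i + 1][lj]
                trans = switch_cost if lj != li else 0.0
                dsw = 1 if lj != li else 0
                # prefer lower cost, then fewer switches, then label A (index 0)
                cands.append(((pen + trans + c, sw + dsw, lj), lj))
            (cost, sw, _), lj = min(cands)
            best[i][li] = (cost, sw)
            choice[i][li] = lj

    # pick the first label: lower cost, fewer switches, then host parent A
    start = min(range(2), key=lambda li: (best[0][li][0], best[0][li][1], li))
    path = [start]
    for i in range(n - 1):
        path.append(choice[i][path[-1]])
    lab_seq = [labels[li] for li in path]

    segments: list[MosaicSegment] = []
    seg_start = 0
    for i in range(1, n + 1):
        if i == n or lab_seq[i] != lab_seq[seg_start]:
            segments.append(MosaicSegment(lab_seq[seg_start], seg_start, i - 1))
            seg_start = i
    breakpoints = [
        BreakpointInterval(
            left=sites[prev.last_site].column,
            right=sites[nxt.first_site].column,
        )
        for prev, nxt in zip(segments, segments[1:])
    ]
    n_mismatch = sum(
        1
        for site, lab in zip(sites, lab_seq)
        if _site_penalty(site.state, lab, 1.0) > 0
    )
    cost = best[0][start][0]
    return MosaicPath(segments, breakpoints, n_mismatch, cost, labels=lab_seq)


def boundary_points(path: MosaicPath, aln: TripleAlignment) -> list[int]:
    """Boundary points in the recombinant's ungapped 1-based coordinates.

    The boundary of each crossover is the first discriminating nucleotide
    assigned to the new parent. Discriminating sites are gap-free columns, so
    the recombinant position is always defined.
    """
    points = []
    for bp in path.breakpoints:
        pos = aln.pos_of(0, bp.boundary_point)
        assert pos is not None
        points.append(pos + 1)
    return points


def call_chimera_class(path: MosaicPath, sites: list[DiscriminatingSite]) -> str:
    """Classify the recombinant relative to the host parent A.

    ``intact``: no site matches the donor; ``full_replacement``: no site
    matches the host; ``chimera``: both parents contribute. Sites matching
    neither parent (candidate point mutations) are ignored for classing.
    """
    has_a = any(s.state is SiteState.MATCHES_A for s in sites)
    has_b = any(s.state is SiteState.MATCHES_B for s in sites)
    if has_a and has_b:
        return "chimera"
    if has_b:
        return "full_replacement"
    return "intact"
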