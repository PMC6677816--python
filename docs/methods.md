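# Methods

## Problem setting

A chimeric 16S rRNA gene is a mosaic of two parental genes produced by
homologous recombination. Because recombination requires local sequence
identity, the only observable evidence of parental origin lies at the
*discriminating sites* — aligned positions where the two parents differ.
Everything this package infers (breakpoints, homology tracts, segment-age
localisation) is a function of those sites; everything it simulates is
designed to produce data whose ground truth is expressible in the same
observable terms.

## Alignment layer

Pairwise global alignment uses affine-gap Needleman–Wunsch scoring
(Biopython's `PairwiseAligner`): match +2, mismatch −1, gap open −5, gap
extend −1, where a gap of length *k* scores `open + (k−1)·extend`. Among
co-optimal alignments the aligner's first traceback is taken, so output is
deterministic for fixed input. The three-way alignment anchors both parents
on the recombinant: each parent is aligned to the recombinant, parent
insertions are emitted as separate columns (host-parent insertions before
donor-parent insertions at the same junction) and are not aligned to each
other — sufficient for site calling, which ignores gapped columns anyway.

Percent identity supports three denominators: all columns, gap-free columns
only, and the default that excludes terminal-gap overhangs (published
identity tables rarely state their convention; the flag lets users match
any of the common ones).

## Mosaic inference

Site *i* carries a state in {matches-host, matches-donor, matches-neither}.
An assignment of sites to parents costs
`switch_cost · (#label changes) + mismatch_cost · (#contradicted sites)`;
matches-neither contradicts both labels equally. The optimum is found by
dynamic programming over sites × {host, donor} (exact; verified against
enumeration of all 2ⁿ assignments for n ≤ 12). Ties are broken
deterministically: fewest segments first, then the first segment assigned
to the host.

Defaults `switch_cost=2, mismatch_cost=1` encode the judgement that an
isolated non-parental base — or a single discriminating site matching the
other parent — is more plausibly a point mutation than a pair of extra
crossovers. For mutation-free simulated data the right setting is a
dominant mismatch penalty (`mismatch_cost ≫ switch_cost`): with no
mutations, every donor-matching base is recombination, and inference then
tracks site states exactly. Validation and the acceptance script use
`switch_cost=1, mismatch_cost=100` on mutation-free benchmarks and the
defaults on mutated ones.

Each crossover is reported as the boundary point (first discriminating
nucleotide of the new parent, the field's convention) and as the ambiguity
interval between the flanking discriminating sites — the true crossover is
fundamentally unidentifiable inside the shared tract, so the interval, not
the point, is the honest object.

## Stretches and breakpoint homology

Shared stretches are maximal runs of identical, gap-free columns between
the parents; gaps terminate a stretch because a crossover needs contiguous
identity. The homology length of a breakpoint is the full length of the
stretch lying strictly between its flanking discriminating sites (not the
interval width minus one): the crossover can have occurred anywhere in the
identical tract. If alignment gaps split that span into several stretches
the longest is attributed; adjacent discriminating sites yield a
zero-length sentinel. Both the tract length and the interval width are
available, since published "minimum identity" figures may follow either
convention.

## Segment mapping

Accretion-model segment coordinates are user-supplied (TSV, 1-based
inclusive, or BED); the test fixture and the acceptance script use a
synthetic 12-segment annotation with randomly permuted age ranks — no real
annotation is baked in. Boundary points are transferred to reference
coordinates through a pairwise alignment (nearest 5′ reference position,
flagged, when the reference is gapped at the matched column). A point on a
segment edge belongs to the segment containing that exact position;
per-segment counts plus the unassigned count always sum to the input size.

## Composition statistics

Columns of a homolog alignment are classed gapped / consensus /
discriminating; "discriminating" defaults to not-unanimous across the
compared set, with a pairwise-vs-focal alternative behind a flag. GC% is
reported per sequence per class; a class with zero columns is undefined
(None), never 0. Identity check: the column-count-weighted combination of
class GC equals the whole gap-free-sequence GC exactly.

## Simulator

The simulator mimics gene replacement in a polyploid, naturally competent
host (default ploidy 4; real strains are polyploid with unreported copy
number, so this is configurable).

1. **Integration.** The locus is `5′ flank + host gene + 3′ flank`; the
   construct is the same with the donor gene. Flanks are host-identical,
   default 400 bases — large enough to dwarf `l_min` while keeping loci
   compact. Two distinct crossover positions are drawn uniformly over bases
   lying in shared identity runs of length ≥ `l_min` (default 9) between
   locus and construct, and the enclosed segment is copied onto one genome
   copy. Uniformity encodes "no positional preference beyond homology".
   Host and donor genes must be equal length (the generator's pairs are;
   indel-carrying real pairs would need an anchored coordinate frame the
   simulator does not model).
2. **Conversion cycles** (default 3): per cycle a random ordered copy pair
   is chosen; the tract start is uniform over eligible bases between those
   two copies, the length geometric with mean 300 bases (unreported in
   real systems; exposed in the config), and the tract end snaps forward
   to the next eligible base (or the locus end). Sequence and
   parent-of-origin labels are copied together.
3. **Resolution**: one copy is fixed across the genome (uniform choice by
   default, or majority with random tie-break), modelling the observed
   instability of the heterozygous ("Hetero") polyploid state. Point
   mutations (default rate 0) are applied to the emitted sequence *after*
   truth extraction.

**Ground truth is observable truth.** Labels are projected onto the
discriminating positions of the gene; a truth crossover is recorded only
where the projected state changes, at the first mechanistic label-change
base inside the flanked gap. Crossovers inside tracts where the parents
are identical are mechanistically real but leave no sequence trace and are
deliberately not truth rows — no inference method could recover them, and
counting them would make recovery metrics meaningless.

**Enrichment** is deterministic exponential competition: each
cultivation-dilution cycle the culture regrows by fold `1/dilution`
(default 1000×, five cycles); the cycle time solves
`Σᵢ fᵢ·exp(rᵢt) = 1/dilution` (Brent root-finding), each genotype is
multiplied by `exp(rᵢt)` and frequencies renormalised. For two genotypes
with rate ratio 2 the per-cycle update has a closed-form quadratic root,
used as an independent oracle.

What the simulator does **not** emulate: indels between parents, biased
crossover placement (e.g. structure-coupled hotspots), fitness-coupled
resolution, transformation efficiency, and within-culture population
genetics. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated mechanism, not performance on real
chimera collections with alignment ambiguity or selection.

## Growth fitting

Doubling time is `ln 2 / slope` of an ordinary least-squares line on
(time, ln OD600). The automatic window scans all contiguous subsequences of
≥ 4 points with positive slope and keeps the highest R² (ties: longer, then
earlier — so a noise-free exponential is fitted over its full extent). A
non-positive slope yields a no-growth marker rather than a number. The fit
is invariant to OD rescaling and time shifts.

## Problem sizes and numerics

Validation uses parent pairs of 1500 bases at 85.9% identity and 60% GC
(typical of moderately divergent 16S pairs), 100-clone benchmarks, 500
random DP instances with n ≤ 12 sites, and 200 random gapped pairs for
stretch checks. The DP is exact, so agreement thresholds are 100%;
enrichment matches its closed form to ~10⁻¹⁵ relative (float64 round-off);
the GC partition identity is exact in rationals and checked to 10⁻⁹
relative. Seeds are threaded through a single `numpy` generator per
workflow: identical config + seed ⇒ byte-identical benchmark output.

## Known limitations

- Three-way alignment is recombinant-anchored merging, not a true MSA;
  parent-vs-parent insertions at the same junction are stacked, not
  aligned.
- Only two candidate parents are modelled; multi-parent mosaics and
  sliding-window/probabilistic recombination detection are out of scope.
- The boundary tally can be grouped per clone or per unique chimera;
  the package reports per-input-sequence counts and leaves deduplication
  to the caller.
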