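"""Synthetic parent pairs and a mechanistic simulator of 16S chimerization.

The simulator mimics gene replacement in a naturally competent polyploid
thermophile. A targeting construct (host-identical 5' flank + donor gene +
host-identical 3' flank) first integrates into one genome copy by a double
crossover (intergenic recombination); iterative intragenomic gene-conversion
cycles then shuttle tracts between the heterozygous copies; the polyploid
state finally resolves to homogeneity by fixing one copy. Every crossover is
constrained to a shared identity stretch of at least ``l_min`` contiguous
bases — the homology requirement of recombination — and every event is
recorded, so the output carries exact ground truth for benchmarking
breakpoint inference.

Ground truth is *observable* truth: per-base parent-of-origin labels are
projected onto the discriminating positions (where the parents differ); a
crossover is recorded only where the projected state switches. Mechanistic
crossovers inside tracts where the parents are identical leave no sequence
trace and are therefore not truth rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .seqcore import SequenceRecord, write_fasta

BASES = np.array(list("ACGT"))
_GC_IDX = np.array([False, True, True, False])  # A C G T


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the chimerization simulator.

    ploidy
        genome copies per cell (the host is polyploid).
    l_min
        minimum shared-stretch length (bases) hosting a crossover.
    flank_len
        host-identical homology flank on the integrating construct (bases).
    conversion_cycles
        iterations of intragenomic copy-to-copy conversion.
    tract_mean
        mean of the geometric conversion-tract length distribution (bases).
    mutation_rate
        per-base substitution probability applied to the resolved sequence.
    dilution / n_cycles
        serial-enrichment bottleneck per cycle and number of cycles.
    """

    ploidy: int = 4
    l_min: int = 9
    flank_len: int = 400
    conversion_cycles: int = 3
    tract_mean: float = 300.0
    mutation_rate: float = 0.0
    dilution: float = 1e-3
    n_cycles: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.l_min < 1:
            raise ValueError("l_min must be >= 1")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0 < self.dilution <= 1:
            raise ValueError("dilution must be in (0, 1]")


@dataclass
class GenomeState:
    """Multi-copy gene-locus state with per-base parent-of-origin labels.

    ``copies[k]`` is a byte array over the locus (flank + gene + flank);
    ``labels[k]`` holds 0 (host) / 1 (donor) per base. The host gene and
    donor gene strings are kept for observable-truth projection.
    """

    copies: list[np.ndarray]
    labels: list[np.ndarray]
    gene_start: int  # locus offset of the gene, 0-based
    gene_end: int  # half-open
    host_gene: str
    donor_gene: str

    @property
    def ploidy(self) -> int:
        return len(self.copies)

    @property
    def heterozygous(self) -> bool:
        first = self.copies[0]
        return any(not np.array_equal(c, first) for c in self.copies[1:])

    def gene_sequence(self, k: int) -> str:
        return "".join(chr(c) for c in self.copies[k][self.gene_start : self.gene_end])


@dataclass(frozen=True)
class ChimeraTruth:
    """Observable ground truth for one resolved clone."""

    final_sequence: str  # gene region, after any point mutations
    true_crossover_positions: tuple[int, ...]  # 1-based, strictly increasing
    outcome_class: str  # intact | chimera | full_replacement
    labels_rle: tuple[tuple[str, int], ...] = ()  # run-length encoded origin


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p_gc = gc / 100.0
    p = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def make_parent_pair(
    length: int,
    target_identity: float,
    gc: float = 50.0,
    placement: str = "uniform",
    seed=0,
) -> tuple[SequenceRecord, SequenceRecord]:
    """Generate a host/donor pair at a controlled ungapped percent identity.

    The host is drawn base-by-base at the requested GC content; the donor is
    the host with ``round(length * (1 - identity/100))`` substitutions, each
    to a different base, placed uniformly or in clusters. Realized identity
    is exact to the rounding of that count (well within +-0.5 points).
    Deterministic per seed.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    if not 0 <= gc <= 100:
        raise ValueError("gc must be in [0, 100]")
    rng = _rng(seed)
    n_diff = int(round(length * (1 - target_identity / 100.0)))
    if n_diff > length:
        raise ValueError("infeasible identity target")
    host = _random_seq(length, gc, rng)

    if placement == "uniform":
        positions = rng.choice(length, size=n_diff, replace=False)
    elif placement == "clustered":
        n_clusters = max(1, n_diff // 20)
        centers = rng.choice(length, size=n_clusters, replace=False)
        chosen: set[int] = set()
        while len(chosen) < n_diff:
            c = centers[rng.integers(n_clusters)]
            p = int(np.clip(round(rng.normal(c, 15.0)), 0, length - 1))
            chosen.add(p)
        positions = np.array(sorted(chosen))
    else:
        raise ValueError(f"unknown placement {placement!r}")

    donor = host.copy()
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    for p in positions:
        alternatives = letters[letters != host[p]]
        donor[p] = rng.choice(alternatives)
    h = host.tobytes().decode()
    d = donor.tobytes().decode()
    return (
        SequenceRecord("host", h, f"synthetic parent, gc={gc}"),
        SequenceRecord("donor", d, f"synthetic parent, identity={target_identity}"),
    )


def _identity_runs(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [s, e) where equal-length arrays a and b agree."""
    eq = a == b
    runs = []
    s = None
    for i in range(len(eq) + 1):
        on = i < len(eq) and eq[i]
        if on and s is None:
            s = i
        if not on and s is not None:
            runs.append((s, i))
            s = None
    return runs


def _eligible_positions(a: np.ndarray, b: np.ndarray, l_min: int) -> np.ndarray:
    """All positions lying in a shared identity run of length >= l_min."""
    pos = [
        np.arange(s, e) for s, e in _identity_runs(a, b) if e - s >= l_min
    ]
    return np.concatenate(pos) if pos else np.array([], dtype=int)


def _observable_truth(state: GenomeState, copy_idx: int) -> ChimeraTruth:
    """Project one copy's labels onto discriminating positions (see module doc)."""
    host = np.frombuffer(state.host_gene.encode(), dtype=np.uint8)
    donor = np.frombuffer(state.donor_gene.encode(), dtype=np.uint8)
    seq = state.copies[copy_idx][state.gene_start : state.gene_end]
    labels = state.labels[copy_idx][state.gene_start : state.gene_end]
    disc = np.nonzero(host != donor)[0]
    if disc.size == 0:
        return ChimeraTruth(seq.tobytes().decode(), (), "intact", _rle(labels, host, donor, seq))
    states = np.where(seq[disc] == host[disc], 0, 1)  # 0 host, 1 donor
    crossovers = []
    for k in range(1, len(disc)):
        if states[k] != states[k - 1]:
            lo, hi = disc[k - 1], disc[k]
            # first mechanistic label change inside (lo, hi]
            seg = labels[lo : hi + 1]
            changes = np.nonzero(np.diff(seg) != 0)[0]
            p = lo + 1 + changes[0] if changes.size else hi
            crossovers.append(int(p) + 1)  # 1-based first base of the new tract
    if not states.any():
        outcome = "intact"
    elif states.all():
        outcome = "full_replacement"
    else:
        outcome = "chimera"
    return ChimeraTruth(
        seq.tobytes().decode(),
        tuple(crossovers),
        outcome,
        _rle(labels, host, donor, seq),
    )


def _rle(labels, host, donor, seq) -> tuple[tuple[str, int], ...]:
    names = {0: "host", 1: "donor"}
    out = []
    for lab in labels:
        name = names[int(lab)]
        if out and out[-1][0] == name:
            out[-1][1] += 1
        else:
            out.append([name, 1])
    return tuple((n, int(c)) for n, c in out)


def simulate_integration(
    host: SequenceRecord,
    donor: SequenceRecord,
    config: SimulationConfig,
    rng=None,
    crossovers: tuple[int, int] | None = None,
) -> tuple[GenomeState, "ChimeraTruth"]:
    """Double-crossover integration of the targeting construct into one copy.

    The host locus is flank5 + host gene + flank3 and the construct is
    flank5 + donor gene + flank3 with host-identical flanks. Two distinct
    crossover positions are drawn uniformly over bases lying in shared
    stretches of length >= l_min between locus and construct; the segment
    between them is replaced by construct sequence on one genome copy.
    Host and donor genes must be the same length (the generator's pairs are).
    Explicit ``crossovers=(c1, c2)`` (0-based locus positions, c1 < c2)
    override the random draw; they must still lie in eligible stretches.
    """
    if len(host.residues) != len(donor.residues):
        raise ValueError("host and donor genes must have equal length")
    rng = _rng(rng if rng is not None else config.seed)
    f = config.flank_len
    flank5 = _random_seq(f, 60.0, rng).tobytes().decode()
    flank3 = _random_seq(f, 60.0, rng).tobytes().decode()
    locus = np.frombuffer((flank5 + host.residues + flank3).encode(), dtype=np.uint8)
    construct = np.frombuffer((flank5 + donor.residues + flank3).encode(), dtype=np.uint8)

    eligible = _eligible_positions(locus, construct, config.l_min)
    if eligible.size < 2:
        raise ValueError(f"no homology >= L_min={config.l_min} between locus and construct")
    if crossovers is not None:
        c1, c2 = crossovers
        if not (c1 < c2 and c1 in eligible and c2 in eligible):
            raise ValueError("forced crossovers must be ordered eligible positions")
    else:
        c1, c2 = np.sort(rng.choice(eligible, size=2, replace=False))

    gene_start, gene_end = f, f + len(host.residues)
    copies = [locus.copy() for _ in range(config.ploidy)]
    labels = [np.zeros(len(locus), dtype=np.int8) for _ in range(config.ploidy)]
    copies[0][c1:c2] = construct[c1:c2]
    labels[0][c1:c2] = 1
    state = GenomeState(
        copies, labels, gene_start, gene_end, host.residues, donor.residues
    )
    return state, _observable_truth(state, 0)


def apply_conversion(state: GenomeState, src: int, dst: int, start: int, end: int) -> None:
    """Overwrite recipient copy `dst` with copy `src` over tract [start, end)."""
    state.copies[dst][start:end] = state.copies[src][start:end]
    state.labels[dst][start:end] = state.labels[src][start:end]


def simulate_conversion_cycles(
    state: GenomeState, config: SimulationConfig, rng=None
) -> GenomeState:
    """Iterative intragenomic gene conversion between genome copies.

    Per cycle a donor copy, a recipient copy and a tract are sampled; the
    tract start is uniform over bases in shared stretches >= l_min between
    the two copies, the length is geometric with mean ``tract_mean``, and the
    tract end snaps forward to the next base inside a shared stretch (or the
    locus end). The recipient's tract (sequence and labels) is overwritten.
    A cycle is a no-op when the chosen copies are identical.
    """
    if state.ploidy < 2:
        raise ValueError("conversion requires ploidy >= 2")
    rng = _rng(rng if rng is not None else config.seed)
    n = state.ploidy
    for _ in range(config.conversion_cycles):
        src, dst = rng.choice(n, size=2, replace=False)
        a, b = state.copies[src], state.copies[dst]
        if np.array_equal(a, b):
            continue
        eligible = _eligible_positions(a, b, config.l_min)
        if eligible.size == 0:
            continue
        start = int(rng.choice(eligible))
        length = int(rng.geometric(1.0 / config.tract_mean))
        target = start + length
        ahead = eligible[eligible >= target]
        end = int(ahead[0]) + 1 if ahead.size else len(a)
        apply_conversion(state, src, dst, start, end)
    return state


def resolve_to_homogeneity(
    state: GenomeState,
    mode: str = "random_fix",
    rng=None,
    mutation_rate: float = 0.0,
) -> ChimeraTruth:
    """Fix one copy across the polyploid genome and emit its ground truth.

    random_fix picks a copy uniformly; majority_fix picks the most common
    copy sequence (ties resolved uniformly among the tied sequences). Point
    mutations at ``mutation_rate`` per base are applied to the returned gene
    sequence after truth extraction, emulating Taq/sequencing-era noise.
    """
    rng = _rng(rng if rng is not None else 0)
    n = state.ploidy
    if mode == "random_fix":
        k = int(rng.integers(n))
    elif mode == "majority_fix":
        keys = [c.tobytes() for c in state.copies]
        counts: dict[bytes, int] = {}
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        top = max(counts.values())
        tied = sorted({key for key, c in counts.items() if c == top})
        pick = tied[int(rng.integers(len(tied)))]
        k = keys.index(pick)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for j in range(n):
        state.copies[j] = state.copies[k].copy()
        state.labels[j] = state.labels[k].copy()
    truth = _observable_truth(state, k)
    if mutation_rate > 0:
        seq = np.frombuffer(truth.final_sequence.encode(), dtype=np.uint8).copy()
        letters = np.frombuffer(b"ACGT", dtype=np.uint8)
        hits = np.nonzero(rng.random(len(seq)) < mutation_rate)[0]
        for p in hits:
            seq[p] = rng.choice(letters[letters != seq[p]])
        truth = replace(truth, final_sequence=seq.tobytes().decode())
    return truth


def simulate_enrichment(
    fitness: dict[str, float],
    init_freq: dict[str, float],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Deterministic serial-dilution growth competition.

    Each cycle the culture regrows from the dilution bottleneck to fixed
    density (fold growth 1/dilution); the cycle time t solves
    ``sum_i f_i * exp(r_i t) = 1/dilution`` and each genotype is multiplied
    by ``exp(r_i t)`` before renormalization. Returns the frequency
    trajectory over cycles 0..n_cycles (rows) per genotype (columns).
    """
    from scipy.optimize import brentq

    names = list(fitness)
    rates = np.array([fitness[g] for g in names], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("growth rates must be positive")
    freqs = np.array([init_freq[g] for g in names], dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("initial frequencies must sum to 1")
    fold = 1.0 / config.dilution
    traj = [freqs.copy()]
    for _ in range(config.n_cycles):
        def density(t):
            return float(np.dot(freqs, np.exp(rates * t))) - fold

        t_hi = np.log(fold) / rates.min() + 1e-9
        t_cycle = brentq(density, 0.0, t_hi, xtol=1e-15, rtol=1e-15)
        freqs = freqs * np.exp(rates * t_cycle)
        freqs = freqs / freqs.sum()
        traj.append(freqs.copy())
    return pd.DataFrame(traj, columns=names, index=pd.RangeIndex(len(traj), name="cycle"))


def simulate_clone(
    host: SequenceRecord,
    donor: SequenceRecord,
    config: SimulationConfig,
    rng,
) -> ChimeraTruth:
    """One end-to-end clone: integration, conversion cycles, resolution."""
    state, _ = simulate_integration(host, donor, config, rng)
    simulate_conversion_cycles(state, config, rng)
    return resolve_to_homogeneity(
        state, mode="random_fix", rng=rng, mutation_rate=config.mutation_rate
    )


def generate_benchmark(
    config: SimulationConfig,
    n_clones: int,
    out_fasta: str | os.PathLike,
    out_truth: str | os.PathLike,
    length: int = 1500,
    identity: float = 85.9,
    gc: float = 60.0,
) -> pd.DataFrame:
    """Write an n-clone chimera library with its ground-truth table.

    The FASTA holds each clone's resolved gene plus the two parents; the TSV
    holds clone_id, outcome class, 1-based crossover positions and the
    run-length-encoded parent-of-origin labels. Byte-identical for identical
    config (the config seed drives everything).
    """
    rng = _rng(config.seed)
    host, donor = make_parent_pair(length, identity, gc=gc, seed=rng)
    rows = []
    records = [host, donor]
    for i in range(n_clones):
        truth = simulate_clone(host, donor, config, rng)
        cid = f"clone{i + 1:04d}"
        records.append(SequenceRecord(cid, truth.final_sequence, truth.outcome_class))
        rows.append(
            {
                "clone_id": cid,
                "class": truth.outcome_class,
                "crossovers": ",".join(map(str, truth.true_crossover_positions)),
                "labels_rle": ";".join(f"{n}:{c}" for n, c in truth.labels_rle),
            }
        )
    truth_df = pd.DataFrame(rows, columns=["clone_id", "class", "crossovers", "labels_rle"])
    write_fasta(records, out_fasta)
    truth_df.to_csv(out_truth, sep="\t", index=False)
    return truth_df
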