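"""Parent-pair generation and the polyploid chimerization simulator."""

import numpy as np
import pandas as pd
import pytest

from rrna_mosaic import (
    SimulationConfig,
    apply_conversion,
    generate_benchmark,
    make_parent_pair,
    resolve_to_homogeneity,
    simulate_clone,
    simulate_conversion_cycles,
    simulate_enrichment,
    simulate_integration,
)
from rrna_mosaic.simulate import _eligible_positions


class TestMakeParentPair:
    def test_target_100_gives_identical_pair(self):
        h, d = make_parent_pair(500, 100.0, seed=1)
        assert h.residues == d.residues

    @pytest.mark.parametrize("placement", ["uniform", "clustered"])
    def test_realized_identity_within_half_point(self, placement):
        h, d = make_parent_pair(1500, 85.9, placement=placement, seed=2)
        ident = 100 * sum(a == b for a, b in zip(h.residues, d.residues)) / 1500
        assert 85.4 <= ident <= 86.4

    def test_gc_content_near_target(self):
        h, _ = make_parent_pair(6000, 90.0, gc=62.0, seed=3)
        gc = 100 * sum(c in "GC" for c in h.residues) / 6000
        assert abs(gc - 62.0) < 3.0

    def test_seed_determinism(self):
        a = make_parent_pair(300, 85.0, seed=7)
        b = make_parent_pair(300, 85.0, seed=7)
        c = make_parent_pair(300, 85.0, seed=8)
        assert a[0].residues == b[0].residues and a[1].residues == b[1].residues
        assert a[1].residues != c[1].residues

    def test_invalid_identity_rejected(self):
        with pytest.raises(ValueError):
            make_parent_pair(100, 0.0)


class TestIntegration:
    def test_identical_donor_is_intact_without_discriminating_sites(self, default_config):
        h, d = make_parent_pair(400, 100.0, seed=1)
        _, truth = simulate_integration(h, d, default_config)
        assert truth.outcome_class == "intact"
        assert truth.true_crossover_positions == ()

    def test_crossovers_forced_into_flanks_give_full_donor_gene(
        self, parent_pair, default_config
    ):
        h, d = parent_pair
        f = default_config.flank_len
        c1, c2 = f - 100, f + len(h.residues) + 100
        state, truth = simulate_integration(h, d, default_config, rng=0, crossovers=(c1, c2))
        assert state.gene_sequence(0) == d.residues
        assert truth.outcome_class == "full_replacement"

    def test_crossovers_lie_in_shared_stretches_at_least_l_min(
        self, parent_pair, default_config
    ):
        h, d = parent_pair
        rng = np.random.default_rng(1)
        for _ in range(20):
            state, _ = simulate_integration(h, d, default_config, rng)
            # reconstruct the construct: pure-host locus with the donor gene
            locus = state.copies[1]
            construct = locus.copy()
            construct[state.gene_start : state.gene_end] = np.frombuffer(
                d.residues.encode(), np.uint8
            )
            eligible = set(
                _eligible_positions(locus, construct, default_config.l_min).tolist()
            )
            changes = np.nonzero(np.diff(state.labels[0]) != 0)[0]
            assert len(changes) == 2
            for i in changes:
                assert int(i) + 1 in eligible

    def test_no_homology_raises(self):
        from rrna_mosaic.seqcore import SequenceRecord

        h, _ = make_parent_pair(60, 100.0, seed=2)
        d = SequenceRecord("d", h.residues.translate(str.maketrans("ACGT", "GTAC")))
        # in-gene identity is zero and the 100-base flank runs are < l_min=101
        with pytest.raises(ValueError, match="no homology"):
            simulate_integration(h, d, SimulationConfig(l_min=101, flank_len=100), rng=0)


class TestConversion:
    def test_identical_copies_unchanged(self, parent_pair):
        h, d = parent_pair
        cfg = SimulationConfig(conversion_cycles=5, seed=3)
        state, _ = simulate_integration(h, d, cfg, rng=4)
        # make all copies identical to copy 0
        for k in range(1, state.ploidy):
            apply_conversion(state, 0, k, 0, len(state.copies[0]))
        before = [c.copy() for c in state.copies]
        simulate_conversion_cycles(state, cfg, rng=5)
        for prev, now in zip(before, state.copies):
            assert np.array_equal(prev, now)

    def test_forced_tract_is_exact_splice(self, parent_pair):
        h, d = parent_pair
        cfg = SimulationConfig(ploidy=2, seed=6)
        state, _ = simulate_integration(h, d, cfg, rng=7)
        recipient_before = state.copies[1].copy()
        donor_copy = state.copies[0].copy()
        apply_conversion(state, 0, 1, 500, 900)
        expected = np.concatenate(
            [recipient_before[:500], donor_copy[500:900], recipient_before[900:]]
        )
        assert np.array_equal(state.copies[1], expected)
        assert np.array_equal(state.labels[1][500:900], state.labels[0][500:900])

    def test_every_base_traceable_to_a_parent(self, parent_pair):
        """Mutation-free output is a perfect mosaic of the two parents."""
        h, d = parent_pair
        cfg = SimulationConfig(seed=8)
        rng = np.random.default_rng(8)
        for _ in range(10):
            truth = simulate_clone(h, d, cfg, rng)
            for i, base in enumerate(truth.final_sequence):
                assert base in (h.residues[i], d.residues[i])

    def test_heterozygous_flag(self, parent_pair, default_config):
        h, d = parent_pair
        f = default_config.flank_len
        # crossovers spanning the gene guarantee a sequence difference
        state, _ = simulate_integration(
            h, d, default_config, rng=9, crossovers=(f - 50, f + len(h.residues) + 50)
        )
        assert state.heterozygous  # copy 0 recombined, others pure host
        for k in range(1, state.ploidy):
            apply_conversion(state, 0, k, 0, len(state.copies[0]))
        assert not state.heterozygous


class TestResolution:
    def test_homogeneous_state_is_identity(self, parent_pair, default_config):
        h, d = parent_pair
        state, truth0 = simulate_integration(h, d, default_config, rng=10)
        for k in range(1, state.ploidy):
            apply_conversion(state, 0, k, 0, len(state.copies[0]))
        truth = resolve_to_homogeneity(state, rng=11)
        assert truth.final_sequence == truth0.final_sequence
        assert truth.true_crossover_positions == truth0.true_crossover_positions

    def test_majority_fix_picks_triplicated_copy(self, parent_pair, default_config):
        h, d = parent_pair
        state, _ = simulate_integration(h, d, default_config, rng=12)
        # ploidy 4: copies 1..3 are pure host -> majority beats the recombinant
        truth = resolve_to_homogeneity(state, mode="majority_fix", rng=13)
        assert truth.outcome_class == "intact"
        assert truth.final_sequence == h.residues

    def test_random_fix_frequencies_match_multiplicity(self, parent_pair, default_config):
        h, d = parent_pair
        n_trials = 400
        hits = 0
        for i in range(n_trials):
            state, _ = simulate_integration(h, d, default_config, rng=100)
            truth = resolve_to_homogeneity(state, mode="random_fix", rng=1000 + i)
            if truth.outcome_class != "intact":
                hits += 1  # fixed the single recombined copy (multiplicity 1/4)
        p = 1 / default_config.ploidy
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(hits / n_trials - p) < 3 * se


class TestEnrichment:
    def test_equal_rates_leave_frequencies_constant(self):
        cfg = SimulationConfig()
        traj = simulate_enrichment({"a": 1.0, "b": 1.0}, {"a": 0.3, "b": 0.7}, cfg)
        assert np.allclose(traj["a"], 0.3) and np.allclose(traj["b"], 0.7)

    def test_two_genotype_rate_ratio_2_matches_closed_form(self):
        """Per cycle f1*x + f2*x^2 = 1/dilution has a quadratic closed form."""
        cfg = SimulationConfig(dilution=1e-3, n_cycles=5)
        r1, r2 = 0.7, 1.4
        traj = simulate_enrichment({"slow": r1, "fast": r2}, {"slow": 0.9, "fast": 0.1}, cfg)
        F = 1.0 / cfg.dilution
        f1, f2 = 0.9, 0.1
        expected = [(f1, f2)]
        for _ in range(5):
            x = (-f1 + np.sqrt(f1 * f1 + 4 * f2 * F)) / (2 * f2)
            g1, g2 = f1 * x, f2 * x * x
            f1, f2 = g1 / (g1 + g2), g2 / (g1 + g2)
            expected.append((f1, f2))
        got = traj[["slow", "fast"]].to_numpy()
        assert np.allclose(got, np.array(expected), rtol=1e-12, atol=0)

    def test_frequencies_form_a_simplex_every_cycle(self):
        cfg = SimulationConfig(n_cycles=8)
        traj = simulate_enrichment(
            {"a": 0.5, "b": 1.1, "c": 2.0}, {"a": 0.2, "b": 0.5, "c": 0.3}, cfg
        )
        sums = traj.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (traj.to_numpy() >= 0).all()


class TestMutatedRecovery:
    def test_interval_coverage_at_low_mutation_rate(self):
        """With 1e-3 per-base mutations, >= 95% of true crossovers are
        still covered by inferred intervals under the default costs (which
        absorb isolated non-parental bases as mutations)."""
        from rrna_mosaic import analyze_recombinant

        cfg = SimulationConfig(mutation_rate=0.001, seed=77)
        rng = np.random.default_rng(77)
        host, donor = make_parent_pair(1500, 85.9, gc=60.0, seed=rng)
        tot = cov = 0
        for _ in range(100):
            truth = simulate_clone(host, donor, cfg, rng)
            res = analyze_recombinant(truth.final_sequence, host, donor)
            for p in truth.true_crossover_positions:
                tot += 1
                if any(l < p <= r for l, r in res.intervals):
                    cov += 1
        assert tot > 0
        assert cov / tot >= 0.95


class TestBenchmark:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=21)
        for run in ("x", "y"):
            generate_benchmark(
                cfg, 5, tmp_path / f"{run}.fa", tmp_path / f"{run}.tsv", length=600
            )
        assert (tmp_path / "x.fa").read_bytes() == (tmp_path / "y.fa").read_bytes()
        assert (tmp_path / "x.tsv").read_bytes() == (tmp_path / "y.tsv").read_bytes()

    def test_zero_clones_gives_headers_only(self, tmp_path):
        cfg = SimulationConfig(seed=1)
        df = generate_benchmark(cfg, 0, tmp_path / "z.fa", tmp_path / "z.tsv", length=300)
        assert df.empty
        tsv = pd.read_csv(tmp_path / "z.tsv", sep="\t")
        assert list(tsv.columns) == ["clone_id", "class", "crossovers", "labels_rle"]
        # FASTA still carries the two parents
        from rrna_mosaic import read_fasta

        assert [r.id for r in read_fasta(tmp_path / "z.fa")] == ["host", "donor"]

    def test_truth_crossovers_strictly_increasing(self, tmp_path):
        cfg = SimulationConfig(seed=22)
        df = generate_benchmark(cfg, 20, tmp_path / "b.fa", tmp_path / "b.tsv", length=800)
        for xs in df["crossovers"]:
            if xs:
                pos = [int(v) for v in str(xs).split(",")]
                assert pos == sorted(pos) and len(set(pos)) == len(pos)
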