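"""Generator contracts: determinism, truth invariants, fragmentation."""

import numpy as np
import pytest

from provirome.composition import kmer_frequencies, mae_distance
from provirome.synthetic import (
    Contig,
    SimulationConfig,
    fragment_genomes,
    generate_world,
    split_genome,
)


class TestConfigValidation:
    def test_viral_range_must_fit_genome(self):
        with pytest.raises(ValueError, match="exceeds"):
            SimulationConfig(genome_length_bp=20_000,
                             viral_length_range_bp=(5_000, 40_000))

    def test_minimum_viral_length_one_kb(self):
        with pytest.raises(ValueError, match="1 kb"):
            SimulationConfig(viral_length_range_bp=(500, 30_000))

    def test_fractions_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(alpha_host_mixing=1.5)

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genera=0)


class TestDeterminism:
    def test_same_seed_identical_world(self):
        cfg = SimulationConfig(seed=3, n_genera=2, hosts_per_genus=2,
                               genome_length_bp=50_000,
                               viral_length_range_bp=(5_000, 12_000))
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert [h.sequence for h in w1.hosts] == [h.sequence for h in w2.hosts]
        assert [v.sequence for v in w1.viral_sequences] == [
            v.sequence for v in w2.viral_sequences
        ]
        assert w1.predictions.equals(w2.predictions)
        assert w1.similarity.equals(w2.similarity)
        assert w1.gene_hits.equals(w2.gene_hits)
        assert w1.truth.virus_host == w2.truth.virus_host

    def test_different_seed_different_world(self):
        cfg1 = SimulationConfig(seed=3, n_genera=2, hosts_per_genus=2,
                                genome_length_bp=50_000,
                                viral_length_range_bp=(5_000, 12_000))
        cfg2 = SimulationConfig(seed=4, n_genera=2, hosts_per_genus=2,
                                genome_length_bp=50_000,
                                viral_length_range_bp=(5_000, 12_000))
        assert generate_world(cfg1).hosts[0].sequence != \
            generate_world(cfg2).hosts[0].sequence


class TestWorldStructure:
    def test_no_viruses_degenerate_world(self):
        cfg = SimulationConfig(seed=0, viruses_per_host=0, n_genera=2,
                               hosts_per_genus=2, genome_length_bp=50_000,
                               viral_length_range_bp=(5_000, 12_000))
        world = generate_world(cfg)
        assert world.hosts and not world.viral_sequences
        assert not world.truth.virus_host

    def test_every_virus_maps_to_one_existing_host(self, default_world):
        hosts = set(h.genome_id for h in default_world.hosts)
        for v in default_world.viral_sequences:
            assert default_world.truth.virus_host[v.virus_id] in hosts
        assert len(default_world.truth.virus_host) == len(
            default_world.viral_sequences
        )

    def test_prophage_coordinates_inside_host_contig(self, default_world):
        for host in default_world.hosts:
            for vid, s, e in host.prophages:
                assert 0 <= s < e <= len(host.sequence)
                virus = default_world.virus_by_id()[vid]
                assert host.sequence[s:e] == virus.sequence

    def test_gene_coordinates_inside_their_sequence(self, default_world):
        for v in default_world.viral_sequences:
            for g in v.genes:
                assert 0 <= g.start < g.end <= len(v.sequence)
        for h in default_world.hosts:
            for g in h.genes:
                assert 0 <= g.start < g.end <= len(h.sequence)

    def test_similarity_symmetric_within_families(self, default_world):
        sim = default_world.similarity
        pairs = set(zip(sim.qseqid, sim.sseqid))
        assert all((s, q) in pairs for q, s in pairs)
        # no cross-family hits
        fam = default_world.truth.protein_family
        assert all(fam[q] == fam[s] for q, s in pairs)

    def test_similarity_clears_thresholds(self, default_world):
        sim = default_world.similarity
        assert (sim.bitscore >= 50).all() and (sim.evalue <= 1e-3).all()

    def test_masked_host_sequences_lack_prophages(self, default_world):
        masked = default_world.host_seqs(mask_prophages=True)
        for host in default_world.hosts:
            expect = len(host.sequence) - sum(
                e - s for _, s, e in host.prophages
            )
            assert len(masked[host.genome_id]) == expect

    def test_composition_mixing_recovers_host(self):
        """At alpha = 0.9, nearly every virus sits nearer its own host
        than the median distance to different-order hosts."""
        world = generate_world(
            SimulationConfig(seed=6, n_genera=4, hosts_per_genus=5,
                             alpha_host_mixing=0.9)
        )
        host_v = {h.genome_id: kmer_frequencies(h.sequence, 4)
                  for h in world.hosts}
        lineages = world.host_lineages()
        good = 0
        for v in world.viral_sequences:
            tnf = kmer_frequencies(v.sequence, 4)
            d_host = mae_distance(tnf, host_v[v.genome_id])
            order = lineages[v.genome_id].get("order")
            others = [
                mae_distance(tnf, host_v[g])
                for g in host_v
                if lineages[g].get("order") != order
            ]
            if d_host < np.median(others):
                good += 1
        assert good / len(world.viral_sequences) >= 0.9


class TestFragmentation:
    def test_target_at_genome_length_single_contig(self, small_world):
        world = small_world
        length = len(world.hosts[0].sequence)
        contigs = fragment_genomes(world, max(length, 10**6), seed=0)
        by_genome = {}
        for c in contigs:
            by_genome.setdefault(c.genome_id, []).append(c)
        for host in world.hosts:
            (only,) = by_genome[host.genome_id]
            assert only.sequence == host.sequence

    def test_breakpoints_flanking_prophage_isolate_it(self, default_world):
        host = next(h for h in default_world.hosts if h.prophages)
        vid, s, e = host.prophages[0]
        contigs = split_genome(host, [s, e])
        inner = next(c for c in contigs if c.start == s and c.end == e)
        assert inner.n_host_genes == 0
        assert inner.prophage_ids == (vid,)
        assert inner.fully_viral
        assert default_world.truth.virus_mode[vid] == "integrated"

    def test_fragmentation_reproducible_for_fixed_seeds(self, default_world):
        def rates():
            counts = []
            for seed in range(10):
                contigs = fragment_genomes(default_world, 20_000, seed=seed,
                                           with_sequences=False)
                n = sum(
                    1 for c in contigs
                    if c.fully_viral and c.length_bp > 30_000
                )
                counts.append(n)
            return counts

        assert rates() == rates()

    def test_target_below_one_kb_rejected(self, small_world):
        with pytest.raises(ValueError):
            fragment_genomes(small_world, 500)

    def test_contig_record_properties(self):
        c = Contig("c1", "g1", 100, 400, n_host_genes=0, prophage_ids=("v1",))
        assert c.length_bp == 300 and c.fully_viral


def test_misclassification_rate_decreases_with_threshold(default_world):
    """Bigger size cut-offs disguise fewer integrated prophages."""
    from provirome.curation import prophage_misclassification_rates

    rates = prophage_misclassification_rates(
        default_world, thresholds=(10_000, 20_000, 30_000),
        n_replicates=30, seed=3,
    )
    assert rates[10_000] >= rates[20_000] >= rates[30_000]
    assert rates[10_000] > rates[30_000]
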