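"""k-mer vectors, MAE, codon usage/CAI and the K-S statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from provirome.composition import (
    CodonUsageTable,
    adaptation_experiment,
    cai,
    codon_usage_table,
    kmer_frequencies,
    ks_statistic,
    mae_distance,
    sequence_cai,
    subsample_experiment,
)


class TestKmerFrequencies:
    def test_homopolymer_mononucleotide(self):
        v = kmer_frequencies("AAAA", 1)
        assert v.freqs[0] == 1.0 and v.freqs[1:].sum() == 0.0

    def test_acgt_dimers_by_hand(self):
        # three windows AC, CG, GT -> 1/3 each
        v = kmer_frequencies("ACGT", 2)
        expect = {("A", "C"): 1 / 3, ("C", "G"): 1 / 3, ("G", "T"): 1 / 3}
        bases = "ACGT"
        for i, f in enumerate(v.freqs):
            pair = (bases[i // 4], bases[i % 4])
            assert f == pytest.approx(expect.get(pair, 0.0))

    def test_all_windows_ambiguous_raises(self):
        with pytest.raises(ValueError):
            kmer_frequencies("ANG", 2)

    def test_ambiguous_windows_skipped_not_counted(self):
        v = kmer_frequencies("AANTT", 2)  # valid windows: AA, TT
        assert v.freqs.sum() == pytest.approx(1.0)
        assert v.freqs[0] == pytest.approx(0.5)  # AA

    def test_frequencies_sum_to_one_for_each_k(self, small_world):
        seq = small_world.viral_sequences[0].sequence
        for k in (1, 2, 3, 4):
            assert kmer_frequencies(seq, k).freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_canonical_collapses_reverse_complement(self):
        v = kmer_frequencies("AAACCC", 3, canonical=True)
        w = kmer_frequencies("GGGTTT", 3, canonical=True)
        np.testing.assert_allclose(v.freqs, w.freqs)


class TestMaeDistance:
    def test_identical_vectors_zero(self):
        v = kmer_frequencies("ACGTACGT", 2)
        assert mae_distance(v, v) == 0.0

    def test_hand_case_quarter(self):
        from provirome.composition import KmerVector

        v1 = KmerVector(1, np.array([0.5, 0.5, 0.0, 0.0]))
        v2 = KmerVector(1, np.array([0.25, 0.25, 0.25, 0.25]))
        assert mae_distance(v1, v2) == pytest.approx(0.25, abs=1e-12)

    def test_mismatched_k_raises(self):
        with pytest.raises(ValueError):
            mae_distance(kmer_frequencies("ACGT", 1), kmer_frequencies("ACGT", 2))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_triangle_inequality(self, seed):
        from provirome.composition import KmerVector

        rng = np.random.default_rng(seed)
        a, b, c = (KmerVector(1, rng.dirichlet(np.ones(4))) for _ in range(3))
        assert mae_distance(a, c) <= mae_distance(a, b) + mae_distance(b, c) + 1e-12


class TestCodonUsage:
    def test_two_codon_family_even_usage(self):
        table = codon_usage_table(["AAAAAG"])  # Lys: AAA, AAG
        assert table.frequency["AAA"] == pytest.approx(0.5)
        assert table.relative_adaptiveness["AAA"] == 1.0
        assert table.relative_adaptiveness["AAG"] == 1.0

    def test_skewed_usage_w_ratio(self):
        # AAA four times, AAG once -> f 0.8/0.2, w(AAG) = 0.25
        table = codon_usage_table(["AAA" * 4 + "AAG"])
        assert table.relative_adaptiveness["AAG"] == pytest.approx(0.25, abs=1e-12)

    def test_single_codon_family_w_is_one(self):
        table = codon_usage_table(["ATGATG"])
        assert table.relative_adaptiveness["ATG"] == 1.0

    def test_bad_length_names_offender(self):
        with pytest.raises(ValueError, match="gene_x"):
            codon_usage_table({"gene_x": "AAAA"})

    def test_unseen_codon_in_seen_family_floored(self):
        table = codon_usage_table(["AAA" * 10])
        assert table.relative_adaptiveness["AAG"] == pytest.approx(1e-3)


class TestCai:
    def test_optimal_gene_scores_one(self):
        table = codon_usage_table(["AAA" * 4 + "AAG"])
        assert cai("AAAAAA", table) == pytest.approx(1.0)

    def test_hand_geometric_mean(self):
        table = CodonUsageTable({}, {"AAA": 1.0, "AAG": 0.25})
        assert cai("AAAAAG", table) == pytest.approx(0.5, abs=1e-12)

    def test_appending_optimal_codon_never_decreases(self):
        table = CodonUsageTable({}, {"AAA": 1.0, "AAG": 0.25, "GGC": 1.0})
        assert cai("AAAAAGGGC", table) >= cai("AAAAAG", table)

    def test_only_excluded_codons_raises(self):
        table = codon_usage_table(["AAAAAG"])
        with pytest.raises(ValueError):
            cai("ATGTGG", table)  # Met + Trp only

    def test_own_genes_beat_shuffled_genes(self, small_world):
        """A genome's CAI against its own table exceeds a shuffled version."""
        host = small_world.hosts[0]
        genes = [host.sequence[g.start : g.end] for g in host.genes[:40]]
        table = codon_usage_table(genes)
        rng = np.random.default_rng(0)
        shuffled = []
        for g in genes:
            codons = [g[i : i + 3] for i in range(0, len(g), 3)]
            # permute bases within the gene: kills codon structure
            flat = list("".join(codons))
            rng.shuffle(flat)
            shuffled.append("".join(flat[: 3 * (len(flat) // 3)]))
        assert sequence_cai(genes, table) >= sequence_cai(shuffled, table)


class TestKsStatistic:
    def test_disjoint_supports_give_one(self):
        assert ks_statistic([1, 2], [3, 4]) == 1.0

    def test_interleaved_hand_case(self):
        assert ks_statistic([1, 3], [2, 4]) == pytest.approx(0.5, abs=1e-12)

    def test_identical_samples_zero(self):
        assert ks_statistic([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 0.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_scipy_two_sample(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 30))
        b = rng.normal(loc=0.3, size=rng.integers(2, 30))
        assert ks_statistic(a, b) == pytest.approx(
            stats.ks_2samp(a, b).statistic, abs=1e-12
        )


class TestAdaptationExperiment:
    def test_distance_category_ordering(self, default_world):
        """K-S separation grows with taxonomic distance from the host."""
        world = default_world
        report = adaptation_experiment(
            world.virus_seqs(), world.host_seqs(), world.truth.virus_host,
            world.host_lineages(), metrics=("k4", "cai"), n_picks=3,
            virus_genes=world.virus_cds(), host_cds=world.host_cds(), seed=0,
        )
        for metric in ("k4", "cai"):
            sub = report[report.metric == metric].set_index("category")["D"]
            assert sub["different_order"] >= sub["same_family"] >= sub["same_genus"]

    def test_fully_adapted_viruses_maximise_separation(self):
        from provirome.synthetic import SimulationConfig, generate_world

        world = generate_world(
            SimulationConfig(seed=4, alpha_host_mixing=1.0, n_genera=4,
                             hosts_per_genus=3)
        )
        report = adaptation_experiment(
            world.virus_seqs(), world.host_seqs(), world.truth.virus_host,
            world.host_lineages(), metrics=("k4",), n_picks=3, seed=0,
        )
        d = report[report.category == "different_order"]["D"].iloc[0]
        assert d > 0.9

    def test_unadapted_viruses_show_null_separation(self):
        from provirome.synthetic import SimulationConfig, generate_world

        world = generate_world(
            SimulationConfig(seed=4, alpha_host_mixing=0.0, n_genera=4,
                             hosts_per_genus=3)
        )
        report = adaptation_experiment(
            world.virus_seqs(), world.host_seqs(), world.truth.virus_host,
            world.host_lineages(), metrics=("k4",), n_picks=3, seed=0,
        )
        row = report[report.category == "different_order"].iloc[0]
        n1, n2 = row["n_virus"], row["n_nonhost"]
        critical = 1.36 * np.sqrt((n1 + n2) / (n1 * n2))  # K-S at p=0.05
        assert row["D"] < critical

    def test_same_seed_reproduces_report(self, small_world):
        world = small_world
        kwargs = dict(
            viruses=world.virus_seqs(), hosts=world.host_seqs(),
            virus_host=world.truth.virus_host,
            host_lineages=world.host_lineages(),
            metrics=("k2",), n_picks=1, seed=9,
        )
        assert adaptation_experiment(**kwargs).equals(adaptation_experiment(**kwargs))

    def test_virus_without_host_raises(self, small_world):
        world = small_world
        with pytest.raises(ValueError, match="lacks a host"):
            adaptation_experiment(
                world.virus_seqs(), world.host_seqs(), {},
                world.host_lineages(), metrics=("k1",),
            )


class TestSubsampleExperiment:
    def test_separation_persists_at_5kb(self, default_world):
        """Host vs non-host signal survives 5 kb fragments for k <= 2."""
        world = default_world
        table, _ = subsample_experiment(
            world.virus_seqs(), world.host_seqs(), world.truth.virus_host,
            world.host_lineages(), sizes=(5_000,), n=150, ks=(1, 2), seed=0,
        )
        for k in (1, 2):
            row = table[table.k == k].iloc[0]
            assert row["mean_host_distance"] < row["mean_nonhost_distance"]

    def test_full_length_fragment_equals_whole_genome(self, small_world):
        world = small_world
        virus = world.viral_sequences[0]
        vid = virus.virus_id
        size = len(virus.sequence)
        table, _ = subsample_experiment(
            {vid: virus.sequence}, world.host_seqs(), world.truth.virus_host,
            world.host_lineages(), sizes=(size,), n=5, ks=(4,), seed=0,
        )
        from provirome.composition import kmer_frequencies, mae_distance

        whole = mae_distance(
            kmer_frequencies(virus.sequence, 4),
            kmer_frequencies(world.host_seqs()[virus.genome_id], 4),
        )
        assert table["mean_host_distance"].iloc[0] == pytest.approx(whole, abs=1e-15)

    def test_oversized_fragments_skipped_with_warning(self, small_world):
        world = small_world
        with pytest.warns(UserWarning, match="skipped"):
            table, _ = subsample_experiment(
                world.virus_seqs(), world.host_seqs(), world.truth.virus_host,
                world.host_lineages(), sizes=(10**7,), n=5, ks=(1,), seed=0,
            )
        assert table.empty

    def test_same_seed_reproduces_table(self, small_world):
        world = small_world
        kwargs = dict(
            viruses=world.virus_seqs(), hosts=world.host_seqs(),
            virus_host=world.truth.virus_host,
            host_lineages=world.host_lineages(),
            sizes=(3_000,), n=20, ks=(2,), seed=4,
        )
        t1, s1 = subsample_experiment(**kwargs)
        t2, s2 = subsample_experiment(**kwargs)
        assert t1.equals(t2) and s1.equals(s2)
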