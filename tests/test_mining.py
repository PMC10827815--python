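"""satDNA discovery: sampling, overlap graph, circularity, consensus, filtering."""

import itertools

import networkx as nx
import numpy as np
import pytest

from satkit import mining, synthetic
from satkit._alignment import revcomp, rotate
from satkit.compare_map import rotational_alignment
from satkit.mining import MiningConfig
from satkit.synthetic import ChromosomeSpec, FamilyPlan, ReadPair


def _tile_reads(template: str, read_len: int = 151, step: int = 10):
    """Reads tiled across a (tandem) template, both strands alternating."""
    reads = []
    for i, start in enumerate(range(0, len(template) - read_len + 1, step)):
        r = template[start:start + read_len]
        reads.append(revcomp(r) if i % 2 else r)
    return reads


class TestSampleReads:
    def test_identity_when_all_requested(self):
        pairs = [ReadPair(str(i), "A" * 10, "C" * 10) for i in range(20)]
        assert mining.sample_reads(pairs, 20, seed=1) == pairs

    def test_seed_deterministic(self):
        pairs = [ReadPair(str(i), "A" * 10, "C" * 10) for i in range(100)]
        s1 = mining.sample_reads(pairs, 30, seed=5)
        s2 = mining.sample_reads(pairs, 30, seed=5)
        assert [p.name for p in s1] == [p.name for p in s2]

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            mining.sample_reads([ReadPair("a", "A", "C")], 2, seed=1)

    def test_two_seed_overlap_near_hypergeometric(self, rng):
        n_lib, n_draw = 2000, 200
        pairs = [ReadPair(str(i), "A", "C") for i in range(n_lib)]
        a = {p.name for p in mining.sample_reads(pairs, n_draw, seed=1)}
        b = {p.name for p in mining.sample_reads(pairs, n_draw, seed=2)}
        expected = n_draw * n_draw / n_lib  # = 20
        assert abs(len(a & b) - expected) < 4 * np.sqrt(expected)


class TestSimilarityGraph:
    def test_identical_reads_edge_identity_one(self, rng):
        r = synthetic._random_seq(151, rng)
        g = mining.build_similarity_graph([r, r])
        assert g.has_edge(0, 1)
        assert g.edges[0, 1]["identity"] == 1.0

    def test_reverse_complement_edge(self, rng):
        r = synthetic._random_seq(151, rng)
        g = mining.build_similarity_graph([r, revcomp(r)])
        assert g.has_edge(0, 1)

    def test_random_reads_no_edge(self, rng):
        reads = [synthetic._random_seq(151, rng) for _ in range(20)]
        g = mining.build_similarity_graph(reads)
        assert g.number_of_edges() == 0


class TestClusterReads:
    def test_components_become_clusters(self, rng):
        fam_a = synthetic._random_seq(300, rng)
        fam_b = synthetic._random_seq(300, rng)
        reads = _tile_reads(fam_a * 3, step=4)[:40] + _tile_reads(fam_b * 3, step=3)[:60]
        g = mining.build_similarity_graph(reads)
        clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), min_cluster_size=25)
        assert [len(c.read_ids) for c in clusters] == [60, 40]

    def test_small_components_dropped(self, rng):
        fam = synthetic._random_seq(300, rng)
        reads = _tile_reads(fam * 3, step=10)[:24]  # one below the default 25
        g = mining.build_similarity_graph(reads)
        assert mining.cluster_reads(g, reads, sum(map(len, reads)), 25) == []
        assert len(mining.cluster_reads(g, reads, sum(map(len, reads)), 20)) == 1

    def test_genome_proportion_estimate(self, rng):
        fam = synthetic._random_seq(300, rng)
        fam_reads = _tile_reads(fam * 4, step=8)
        noise = [synthetic._random_seq(151, rng) for _ in range(100)]
        reads = fam_reads + noise
        g = mining.build_similarity_graph(reads)
        clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), 25)
        expected = len(fam_reads) / len(reads)
        assert clusters[0].genome_proportion == pytest.approx(expected, rel=0.01)


class TestMaxMeanCycleOracle:
    """Exact Karp implementation vs brute-force enumeration on toy graphs."""

    @staticmethod
    def _brute_best_mean(edges, n):
        g = nx.DiGraph()
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        best = None
        for cyc in nx.simple_cycles(g):
            ws = [g.edges[cyc[i], cyc[(i + 1) % len(cyc)]]["weight"]
                  for i in range(len(cyc))]
            mean = sum(ws) / len(ws)
            if best is None or mean > best:
                best = mean
        return best

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        edges = []
        for u, v in itertools.permutations(range(n), 2):
            if rng.random() < 0.4:
                edges.append((u, v, float(rng.integers(1, 20))))
        brute = self._brute_best_mean(edges, n)
        mu, cycle = mining.max_mean_weight_cycle(edges, n)
        if brute is None:
            assert mu is None
        else:
            assert mu == pytest.approx(brute)
            # the returned cycle must achieve the optimum
            wmap = {(u, v): w for u, v, w in edges}
            ws = [wmap[(cycle[i], cycle[(i + 1) % len(cycle)])] for i in range(len(cycle))]
            assert sum(ws) / len(ws) == pytest.approx(brute)

    def test_acyclic_graph_returns_none(self):
        edges = [(0, 1, 5.0), (1, 2, 3.0), (0, 2, 9.0)]
        mu, cycle = mining.max_mean_weight_cycle(edges, 3)
        assert mu is None and cycle is None


class TestCircularityAndConsensus:
    def test_perfect_tandem_scores_high(self, rng):
        mono = synthetic._random_seq(300, rng)
        reads = _tile_reads(mono * 8, step=5)
        g = mining.build_similarity_graph(reads)
        clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), 25)
        score = mining.circularity_score(clusters[0], reads)
        assert score >= 0.8
        assert len(clusters[0].consensus_cycle) == 300

    def test_single_copy_locus_scores_low(self, rng):
        locus = synthetic._random_seq(3000, rng)
        reads = _tile_reads(locus, step=25)
        g = mining.build_similarity_graph(reads)
        clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), 25)
        assert clusters, "tiled reads should chain into one cluster"
        assert mining.circularity_score(clusters[0], reads) <= 0.2

    def test_empty_cluster_scores_zero(self):
        c = mining.ReadCluster([], nx.Graph(), 0.0)
        assert mining.circularity_score(c, []) == 0.0

    def test_consensus_recovers_monomer_exactly(self, rng):
        mono = synthetic._random_seq(300, rng)
        reads = _tile_reads(mono * 8, step=5)
        g = mining.build_similarity_graph(reads)
        clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), 25)
        mon = mining.build_consensus(clusters[0], reads)
        assert mon is not None
        assert mon.unit_length == 300
        assert rotational_alignment(mon.sequence, mono).identity == 100.0

    def test_consensus_with_read_errors_near_exact(self, rng):
        mono = synthetic._random_seq(300, rng)
        tandem = mono * 8
        reads = []
        for i, r in enumerate(_tile_reads(tandem, step=4)):
            reads.append(synthetic._add_errors(r, 0.01, rng))
        g = mining.build_similarity_graph(reads)
        clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), 25)
        mon = mining.build_consensus(clusters[0], reads)
        assert mon.unit_length == 300
        assert rotational_alignment(mon.sequence, mono).identity >= 99.0

    def test_short_cycle_rejected_by_min_monomer(self, rng):
        reads = _tile_reads("TTTAGGG" * 60, step=6)
        g = mining.build_similarity_graph(reads)
        clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), 25)
        mon = mining.build_consensus(clusters[0], reads)
        assert mon is None  # 7 bp cycle < min_monomer

    def test_consensus_reported_in_canonical_rotation(self, rng):
        from satkit._alignment import canonical_rotation

        mono = synthetic._random_seq(250, rng)
        for phase in (0, 60):
            reads = _tile_reads(rotate(mono, phase) * 8, step=5)
            g = mining.build_similarity_graph(reads)
            clusters = mining.cluster_reads(g, reads, sum(map(len, reads)), 25)
            mon = mining.build_consensus(clusters[0], reads)
            assert mon.sequence == canonical_rotation(mono)


class TestFilterReads:
    def test_exact_monomer_read_removed_random_retained(self, rng):
        mono = synthetic._random_seq(300, rng)
        sat = ReadPair("s", (mono * 2)[10:161], synthetic._random_seq(151, rng))
        noise = ReadPair("n", synthetic._random_seq(151, rng),
                         synthetic._random_seq(151, rng))
        kept = mining.filter_reads([sat, noise], [mono])
        assert [p.name for p in kept] == ["n"]  # both mates go when one matches

    def test_below_threshold_read_retained(self, rng):
        mono = synthetic._random_seq(300, rng)
        diverged = synthetic.mutate_sequence((mono * 2)[:151], 0.30, rng)  # ~75% identity
        pair = ReadPair("d", diverged, synthetic._random_seq(151, rng))
        kept = mining.filter_reads([pair], [mono])
        assert kept == [pair]

    def test_filtering_soundness_rescan(self, small_study):
        """After filtering with a monomer, no surviving read matches it."""
        cfg = MiningConfig()
        mono = small_study["truth"].consensus["F1"]
        kept = mining.filter_reads(small_study["pairs"][:500], [mono], cfg)
        targets, kmer_sets = mining._monomer_targets([mono])
        for p in kept:
            assert not mining._read_matches_monomer(p.seq1, targets, kmer_sets, cfg)
            assert not mining._read_matches_monomer(p.seq2, targets, kmer_sets, cfg)


class TestRunSatminer:
    def test_empty_genome_gives_empty_catalog(self, rng):
        chrom = ChromosomeSpec("chr1", 200_000, 80_000, telomere_repeats=0)
        genome, _ = synthetic.plant_genome([chrom], [], seed=3)
        pairs = synthetic.simulate_reads(genome, 1.0, 151, 350, 0.0, seed=4)
        mons, _ = mining.run_satminer(pairs, n_rounds=1, seed=5,
                                      cfg=MiningConfig(min_cluster_size=10))
        assert mons == []

    def test_rare_family_found_after_filtering_round(self):
        """A rare family masked by an abundant one surfaces in a later round."""
        plans = [
            FamilyPlan("Big", 300, n_units_clustered=160,
                       array_loci=[("chr1", "interstitial")], mutation_age=0.02),
            FamilyPlan("Rare", 170, n_units_clustered=18,
                       array_loci=[("chr1", "terminal")], mutation_age=0.02),
        ]
        chrom = ChromosomeSpec("chr1", 400_000, 160_000)
        genome, truth = synthetic.plant_genome([chrom], plans, seed=21)
        pairs = synthetic.simulate_reads(genome, 1.2, 151, 350, 0.002, seed=22)
        cfg = MiningConfig(min_cluster_size=8)
        # keep round samples small so the abundant family dominates round 1
        mons, rounds = mining.run_satminer(pairs, n_rounds=3, pairs_per_round=600,
                                           seed=23, cfg=cfg)
        matches = {}
        for m in mons:
            for fam, cons in truth.consensus.items():
                if rotational_alignment(m.sequence, cons).identity >= 95.0:
                    matches[fam] = m.round_index
        assert matches.get("Big") == 1
        assert "Rare" in matches and matches["Rare"] >= matches["Big"]

    def test_rerun_identical(self, small_study):
        pairs = small_study["pairs"]
        cfg = MiningConfig(min_cluster_size=10)
        m1, _ = mining.run_satminer(pairs, n_rounds=1, seed=9, cfg=cfg)
        m2, _ = mining.run_satminer(pairs, n_rounds=1, seed=9, cfg=cfg)
        assert [(m.name, m.sequence) for m in m1] == [(m.name, m.sequence) for m in m2]

    def test_monotone_discovery_and_round_indices(self, small_study):
        cfg = MiningConfig(min_cluster_size=10)
        mons, rounds = mining.run_satminer(small_study["pairs"], n_rounds=2, seed=9, cfg=cfg)
        per_round = [r.n_new_monomers for r in rounds]
        assert sum(per_round) == len(mons)
        assert all(m.round_index <= len(rounds) for m in mons)
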