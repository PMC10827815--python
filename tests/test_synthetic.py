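"""Synthetic genome generator: monomer construction, planting, read simulation."""

import numpy as np
import pytest

from satkit import synthetic
from satkit._alignment import revcomp
from satkit.compare_map import rotational_alignment
from satkit.synthetic import ChromosomeSpec, ConfigurationError, FamilyPlan


class TestBuildMonomer:
    def test_length_and_at_content(self):
        plan = FamilyPlan("F", 44, at_target=0.70)
        seq = synthetic.build_monomer(plan, seed=1)
        assert len(seq) == 44
        at = (seq.count("A") + seq.count("T")) / 44
        assert 0.65 <= at <= 0.75

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_subrepeat_structure(self, seed):
        """A 620-bp unit built from a 155-bp subunit carries 4 detectable copies."""
        from satkit.monomer import find_direct_subrepeats

        plan = FamilyPlan("F", 620, subrepeat_period=155)
        seq = synthetic.build_monomer(plan, seed=seed)
        subs = find_direct_subrepeats(seq)
        assert subs, "no subrepeat detected"
        assert subs[0].period == 155
        assert subs[0].copies == 4

    def test_ancestor_divergence(self):
        """A descendant at planted divergence 0.30 shows ~70% rotational identity."""
        a_plan = FamilyPlan("A", 400)
        a = synthetic.build_monomer(a_plan, seed=2)
        b = synthetic.build_monomer(
            FamilyPlan("B", 400, ancestor="A", ancestor_divergence=0.30),
            seed=3, monomers={"A": a},
        )
        ident = rotational_alignment(b, a).identity
        assert 65.0 <= ident <= 80.0

    def test_te_fragment_copied(self):
        te = {"TE1": "ACGT" * 300}
        plan = FamilyPlan("F", 400, te_fragment=("TE1", 0.5))
        seq = synthetic.build_monomer(plan, seed=4, te_library=te)
        assert seq[:200] in te["TE1"]

    def test_unknown_references_raise(self):
        with pytest.raises(ConfigurationError):
            synthetic.build_monomer(FamilyPlan("F", 100, ancestor="nope"), seed=1)
        with pytest.raises(ConfigurationError):
            synthetic.build_monomer(
                FamilyPlan("F", 100, te_fragment=("nope", 0.5)), seed=1, te_library={}
            )

    def test_plan_invariants(self):
        with pytest.raises(ConfigurationError):
            FamilyPlan("F", 9)
        with pytest.raises(ConfigurationError):
            FamilyPlan("F", 100, at_target=1.5)
        with pytest.raises(ConfigurationError):
            FamilyPlan("F", 100, subrepeat_period=60)  # does not divide >= 2x


class TestMutationModel:
    def test_zero_age_identity(self, rng):
        s = synthetic._random_seq(500, rng)
        assert synthetic.mutate_sequence(s, 0.0, rng) == s

    def test_expected_divergence(self, rng):
        s = synthetic._random_seq(20_000, rng)
        m = synthetic.mutate_sequence(s, 0.05, rng)
        pdist = sum(a != b for a, b in zip(s, m)) / len(s)
        # multiple hits make the observed p-distance slightly below the age
        assert 0.04 <= pdist <= 0.055


class TestPlantGenome:
    def test_single_terminal_locus(self):
        plan = FamilyPlan("F", 200, n_units_clustered=10,
                          array_loci=[("chr1", "terminal")])
        chrom = ChromosomeSpec("chr1", 300_000, 120_000)
        genome, truth = synthetic.plant_genome([chrom], [plan], seed=5)
        ivs = truth.intervals["F"]
        assert len(ivs) == 1
        iv = ivs[0]
        w = synthetic._terminal_window(chrom)
        tel = chrom.telomere_repeats * 7
        assert iv.start >= tel and iv.end <= chrom.length - tel
        assert iv.start < tel + w or iv.end > chrom.length - tel - w

    def test_dispersed_units_form_many_loci(self):
        plan = FamilyPlan("F", 50, n_dispersed_units=200)
        chrom = ChromosomeSpec("chr1", 400_000, 150_000)
        _, truth = synthetic.plant_genome([chrom], [plan], seed=6)
        ivs = truth.intervals["F"]
        assert len(ivs) >= 67  # tandems of at most 3 units
        assert sum(iv.n_units for iv in ivs) == 200

    def test_truth_conservation_and_divergence(self):
        plan = FamilyPlan("F", 300, n_units_clustered=60,
                          array_loci=[("chr1", "interstitial")], mutation_age=0.05)
        chrom = ChromosomeSpec("chr1", 400_000, 150_000)
        genome, truth = synthetic.plant_genome([chrom], [plan], seed=7)
        assert truth.planted_bp("F") == 60 * 300
        assert truth.genome_proportion["F"] == pytest.approx(60 * 300 / 400_000)
        assert truth.mean_divergence["F"] == pytest.approx(0.05, abs=0.01)

    def test_telomere_caps_both_ends(self):
        chrom = ChromosomeSpec("chr1", 100_000, 40_000, telomere_repeats=20)
        genome, _ = synthetic.plant_genome([chrom], [], seed=8)
        seq = genome["chr1"]
        assert seq.startswith("TTTAGGG" * 20)
        assert seq.endswith(revcomp("TTTAGGG" * 20))

    def test_reproducible(self):
        plan = FamilyPlan("F", 120, n_units_clustered=20,
                          array_loci=[("chr1", "interstitial")], mutation_age=0.02)
        chrom = ChromosomeSpec("chr1", 200_000, 90_000)
        g1, t1 = synthetic.plant_genome([chrom], [plan], seed=9)
        g2, t2 = synthetic.plant_genome([chrom], [plan], seed=9)
        assert g1 == g2
        assert t1.intervals == t2.intervals

    def test_overfull_genome_rejected(self):
        plan = FamilyPlan("F", 1000, n_units_clustered=60,
                          array_loci=[("chr1", "interstitial")])
        chrom = ChromosomeSpec("chr1", 100_000, 40_000)
        with pytest.raises(ConfigurationError):
            synthetic.plant_genome([chrom], [plan], seed=1)


class TestSimulateReads:
    @pytest.fixture(scope="class")
    def tiny_genome(self):
        chrom = ChromosomeSpec("chr1", 1_000_000, 400_000)
        genome, _ = synthetic.plant_genome([chrom], [], seed=10)
        return genome

    def test_pair_count_matches_coverage(self, tiny_genome):
        pairs = synthetic.simulate_reads(tiny_genome, 1.2, 151, 350, 0.0, seed=1)
        expected = 1.2 * 1e6 / (2 * 151)
        assert abs(len(pairs) - expected) / expected < 0.02

    def test_error_free_reads_are_genomic_substrings(self, tiny_genome):
        pairs = synthetic.simulate_reads(tiny_genome, 0.05, 151, 350, 0.0, seed=2)
        seq = tiny_genome["chr1"]
        for p in pairs:
            assert p.seq1 in seq or revcomp(p.seq1) in seq
            assert p.seq2 in seq or revcomp(p.seq2) in seq

    def test_mates_on_opposite_strands(self, tiny_genome):
        pairs = synthetic.simulate_reads(tiny_genome, 0.05, 100, 300, 0.0, seed=3)
        seq = tiny_genome["chr1"]
        fwd_fwd = sum(1 for p in pairs if p.seq1 in seq and p.seq2 in seq)
        assert fwd_fwd == 0  # one mate is always reverse-complement

    def test_fastq_round_trip_deterministic(self, tiny_genome, tmp_path):
        pairs = synthetic.simulate_reads(tiny_genome, 0.02, 151, 350, 0.01, seed=4)
        p1, p2 = synthetic.write_fastq_pair(pairs, tmp_path / "reads")
        again = synthetic.simulate_reads(tiny_genome, 0.02, 151, 350, 0.01, seed=4)
        q1, q2 = synthetic.write_fastq_pair(again, tmp_path / "reads2")
        assert p1.read_bytes() == q1.read_bytes()
        assert p2.read_bytes() == q2.read_bytes()
        back = synthetic.read_fastq_pair(p1, p2)
        assert [(r.seq1, r.seq2) for r in back] == [(r.seq1, r.seq2) for r in pairs]

    def test_invalid_coverage_rejected(self, tiny_genome):
        with pytest.raises(ConfigurationError):
            synthetic.simulate_reads(tiny_genome, 0.0, 151, 350, 0.0, seed=1)


def test_truth_bed_is_bed6(tmp_path):
    plan = FamilyPlan("FamX", 100, n_units_clustered=10,
                      array_loci=[("chr1", "interstitial")])
    chrom = ChromosomeSpec("chr1", 150_000, 60_000)
    _, truth = synthetic.plant_genome([chrom], [plan], seed=11)
    out = tmp_path / "truth.bed"
    truth.to_bed(out)
    fields = out.read_text().strip().split("\n")[0].split("\t")
    assert len(fields) == 6
    assert fields[0] == "chr1" and fields[3] == "FamX" and fields[4] == "10"
    assert int(fields[1]) < int(fields[2])
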