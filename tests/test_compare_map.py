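"""Family comparison, assembly search, array merging, distribution classes."""

import numpy as np
import pytest

from satkit import compare_map as cm
from satkit import synthetic
from satkit._alignment import revcomp, rotate
from satkit.compare_map import AssemblyHit, TandemArray
from satkit.synthetic import ChromosomeSpec, FamilyPlan


class TestRotationalAlignment:
    def test_rotation_gives_full_identity(self, rng):
        a = synthetic._random_seq(300, rng)
        for off in (0, 10, 150, 299):
            sim = cm.rotational_alignment(a, rotate(a, off))
            assert sim.identity == 100.0
            assert sim.aligned_fraction == pytest.approx(1.0)

    def test_reverse_complement_minus_strand(self, rng):
        a = synthetic._random_seq(300, rng)
        sim = cm.rotational_alignment(a, revcomp(a))
        assert sim.identity == 100.0
        assert sim.strand == "-"

    def test_offset_recovered(self, rng):
        a = synthetic._random_seq(300, rng)
        sim = cm.rotational_alignment(a, rotate(a, 40))
        # a equals rotate(a, 40) shifted by 40: offset identifies the phase
        assert sim.offset % 300 in {40, 260}

    def test_random_pair_low_identity_blocks(self, rng):
        a = synthetic._random_seq(300, rng)
        b = synthetic._random_seq(300, rng)
        sim = cm.rotational_alignment(a, b)
        assert sim.score < 30  # chance blocks stay below the linkage floor

    def test_short_monomer_rejected(self):
        with pytest.raises(ValueError):
            cm.rotational_alignment("ACGT", "ACGTACGTACGTACGTACGT")


class TestSuperfamilies:
    def test_planted_trio_single_sf(self, rng):
        a = synthetic.build_monomer(FamilyPlan("A", 350), seed=1)
        kids = {
            name: synthetic.build_monomer(
                FamilyPlan(name, 350, ancestor="A", ancestor_divergence=0.28),
                seed=s, monomers={"A": a})
            for name, s in (("B", 2), ("C", 3))
        }
        labels = cm.group_superfamilies({"A": a, **kids,
                                         "D": synthetic.build_monomer(FamilyPlan("D", 350), seed=4)})
        assert labels["A"] == labels["B"] == labels["C"] == "SF-1"
        assert labels["D"] is None

    def test_single_linkage_chain(self, monkeypatch):
        """A~B and B~C merge all three even when A!~C."""
        sims = {("A", "B"): 80.0, ("B", "C"): 80.0, ("A", "C"): 20.0}

        def fake(a, b, name_a="A", name_b="B"):
            key = tuple(sorted((name_a, name_b)))
            return cm.PairSimilarity(name_a, name_b, sims[key], 1.0, 0, "+", 200.0)

        monkeypatch.setattr(cm, "rotational_alignment", fake)
        labels = cm.group_superfamilies({"A": "x", "B": "y", "C": "z"})
        assert labels == {"A": "SF-1", "B": "SF-1", "C": "SF-1"}

    def test_unrelated_catalogs_never_merge(self, rng):
        """No false merges across 100 random catalogs at default thresholds."""
        merges = 0
        for _ in range(100):
            cat = {
                f"R{i}": synthetic._random_seq(int(rng.integers(60, 300)), rng,
                                               float(rng.uniform(0.35, 0.7)))
                for i in range(3)
            }
            merges += sum(1 for v in cm.group_superfamilies(cat).values() if v)
        assert merges == 0


class TestTEHomology:
    @pytest.fixture(scope="class")
    def te_lib(self):
        raw = synthetic.load_te_library()
        return {k: (v, "LTR/Copia" if "Copia" in k else "DNA/Other") for k, v in raw.items()}

    def test_planted_fragment_coverage(self, te_lib, rng):
        te = synthetic.load_te_library()
        plan = FamilyPlan("T", 1000, te_fragment=("synTE_Copia-1", 0.5))
        mono = synthetic.build_monomer(plan, seed=7, te_library=te)
        hits = cm.te_homology(mono, te_lib)
        assert hits and hits[0]["te_name"] == "synTE_Copia-1"
        assert hits[0]["coverage"] == pytest.approx(50.0, abs=5.0)
        assert hits[0]["te_class"] == "LTR/Copia"

    def test_full_te_monomer(self, te_lib):
        te = synthetic.load_te_library()
        mono = te["synTE_MuDR-1"][:600]
        hits = cm.te_homology(mono, te_lib)
        assert hits[0]["te_name"] == "synTE_MuDR-1"
        assert hits[0]["coverage"] == pytest.approx(100.0, abs=1.0)

    def test_random_monomer_no_hits(self, te_lib, rng):
        mono = synthetic._random_seq(800, rng)
        assert cm.te_homology(mono, te_lib) == []

    def test_empty_library_warns(self):
        with pytest.warns(UserWarning):
            assert cm.te_homology("ACGT" * 100, {}) == []


class TestSearchAssembly:
    def test_single_exact_copy(self, rng):
        mono = synthetic._random_seq(400, rng)
        bg = synthetic._random_seq(20_000, rng)
        assembly = {"chr1": bg[:8000] + mono + bg[8000:]}
        hits = cm.search_assembly(mono, assembly)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (8000, 8400, "+")
        assert h.identity == 100.0

    def test_minus_strand_on_forward_coordinates(self, rng):
        mono = synthetic._random_seq(400, rng)
        bg = synthetic._random_seq(10_000, rng)
        assembly = {"chr1": bg[:5000] + revcomp(mono) + bg[5000:]}
        hits = cm.search_assembly(mono, assembly)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (5000, 5400, "-")

    def test_planted_tandem_unit_scale_hits(self, rng):
        mono = synthetic._random_seq(300, rng)
        units = [synthetic.mutate_sequence(mono, 0.05, rng) for _ in range(20)]
        assembly = {"chr1": synthetic._random_seq(3000, rng) + "".join(units)
                    + synthetic._random_seq(3000, rng)}
        hits = cm.search_assembly(mono, assembly)
        assert len(hits) >= 18

    def test_absent_monomer_no_hits(self, rng):
        mono = synthetic._random_seq(400, rng)
        assembly = {"chr1": synthetic._random_seq(30_000, rng)}
        assert cm.search_assembly(mono, assembly) == []

    def test_rotated_query_covers_same_array(self, rng):
        """Hit footprints are rotation-invariant at the array level."""
        mono = synthetic._random_seq(300, rng)
        assembly = {"chr1": synthetic._random_seq(2000, rng) + mono * 20
                    + synthetic._random_seq(2000, rng)}
        def covered(hits):
            mask = np.zeros(10_000, bool)
            for h in hits:
                mask[h.start:h.end] = True
            return mask
        base = covered(cm.search_assembly(mono, assembly))
        rot = covered(cm.search_assembly(rotate(mono, 123), assembly))
        jaccard = (base & rot).sum() / (base | rot).sum()
        assert jaccard >= 0.9


class TestMergeHits:
    def _h(self, start, end, strand="+", chrom="chr1"):
        return AssemblyHit(chrom, start, end, strand, 95.0)

    def test_adjacent_hits_merge_with_unit_count(self):
        hits = [self._h(0, 100), self._h(100, 200), self._h(205, 300)]
        arrays = cm.merge_hits_to_arrays(hits, unit_length=100, max_gap=20)
        assert len(arrays) == 1
        assert arrays[0].n_units == 3
        assert (arrays[0].start, arrays[0].end) == (0, 300)

    def test_distant_hits_stay_apart(self):
        arrays = cm.merge_hits_to_arrays([self._h(0, 100), self._h(10_100, 10_200)], 100)
        assert len(arrays) == 2

    def test_single_hit_single_unit(self):
        arrays = cm.merge_hits_to_arrays([self._h(50, 149)], 100)
        assert arrays[0].n_units == 1

    def test_strand_separation(self):
        hits = [self._h(0, 100, "+"), self._h(100, 200, "-")]
        assert len(cm.merge_hits_to_arrays(hits, 100)) == 2

    def test_idempotent(self, rng):
        hits = []
        pos = 0
        for _ in range(50):
            pos += int(rng.integers(0, 400))
            hits.append(self._h(pos, pos + 100))
            pos += 100
        arrays = cm.merge_hits_to_arrays(hits, 100)
        rehits = [AssemblyHit(a.chromosome, a.start, a.end, a.strand, a.mean_identity)
                  for a in arrays]
        again = cm.merge_hits_to_arrays(rehits, 100)
        assert [(a.start, a.end) for a in again] == [(a.start, a.end) for a in arrays]


class TestTerminalWindows:
    def test_telomere_flags_and_counts(self):
        chroms, plans = synthetic.default_distribution_plans()
        genome, truth = synthetic.plant_genome(chroms, plans[:1], seed=31)
        mono = truth.consensus["TermFam"]
        hits = cm.search_assembly(mono, genome)
        table = cm.scan_terminal_windows(genome, 25_000, {"TermFam": hits})
        for chrom in genome:
            assert table[chrom]["left"]["telomere"]
            assert table[chrom]["right"]["telomere"]
        total_terminal = sum(
            table[c][side]["families"]["TermFam"]
            for c in genome for side in ("left", "right")
        )
        assert total_terminal == len(hits)  # family planted only terminally

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="chr1"):
            cm.scan_terminal_windows({"chr1": "A" * 1000}, 600, {})


class TestClassifyDistribution:
    CHROMS = [ChromosomeSpec(f"chr{i}", 500_000, 225_000) for i in (1, 2, 3, 4)]

    def _arr(self, chrom, start, n_units, unit=300):
        return TandemArray(chrom, start, start + n_units * unit, n_units, 95.0, "+")

    def test_all_terminal(self):
        arrays = [self._arr("chr1", 1000, 20), self._arr("chr2", 495_000 - 6000, 20)]
        call = cm.classify_distribution("f", arrays, self.CHROMS)
        assert call.label == "Terminal"

    def test_all_centromeric(self):
        arrays = [self._arr(c.name, 220_000, 10) for c in self.CHROMS]
        assert cm.classify_distribution("f", arrays, self.CHROMS).label == "(peri)centromeric"

    def test_dispersed_many_minor_loci(self, rng):
        arrays = [self._arr(f"chr{1 + i % 4}", int(rng.integers(30_000, 400_000)), 1)
                  for i in range(500)]
        assert cm.classify_distribution("f", arrays, self.CHROMS).label == "Dispersed"

    def test_mixed_major_loci_multiple_locations(self):
        arrays = [self._arr("chr1", 1000, 20), self._arr("chr2", 100_000, 20)]
        assert cm.classify_distribution("f", arrays, self.CHROMS).label == "Multiple locations"

    def test_no_hits_absent(self):
        assert cm.classify_distribution("f", [], self.CHROMS).label == "absent"

    def test_four_planted_classes_recovered(self):
        chroms, plans = synthetic.default_distribution_plans()
        genome, truth = synthetic.plant_genome(chroms, plans, seed=21)
        expected = {"TermFam": "Terminal", "CenFam": "(peri)centromeric",
                    "MultiFam": "Multiple locations", "DispFam": "Dispersed"}
        for plan in plans:
            mono = truth.consensus[plan.name]
            hits = cm.search_assembly(mono, genome)
            arrays = cm.merge_hits_to_arrays(hits, len(mono))
            call = cm.classify_distribution(plan.name, arrays, chroms)
            assert call.label == expected[plan.name], plan.name
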