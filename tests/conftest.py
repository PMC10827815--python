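"""Shared fixtures.

The expensive full-scale synthetic study (5 Mb genome, 10 planted families,
1.2x coverage, three mining rounds plus landscapes) runs once per session and
backs the recovery-oriented tests.
"""

import numpy as np
import pytest

from satkit import landscape as landscape_mod
from satkit import mining, synthetic


@pytest.fixture(scope="session")
def small_study():
    """A 500 kb genome with three planted families at three ages."""
    plans = [
        synthetic.FamilyPlan("F1", 300, at_target=0.55, n_units_clustered=40,
                             array_loci=[("chr1", "interstitial")], mutation_age=0.03),
        synthetic.FamilyPlan("F2", 150, at_target=0.45, n_units_clustered=60,
                             array_loci=[("chr1", "terminal")], mutation_age=0.05),
        synthetic.FamilyPlan("F3", 400, at_target=0.60, n_units_clustered=30,
                             array_loci=[("chr1", "pericentromeric")], mutation_age=0.12),
    ]
    chrom = synthetic.ChromosomeSpec("chr1", 500_000, 200_000)
    genome, truth = synthetic.plant_genome([chrom], plans, seed=7)
    pairs = synthetic.simulate_reads(genome, 1.2, 151, 350, 0.002, seed=3)
    return {"chromosomes": [chrom], "plans": plans, "genome": genome,
            "truth": truth, "pairs": pairs}


@pytest.fixture(scope="session")
def default_study():
    """The full default study: genome, truth, reads, mined monomers, landscapes."""
    chroms = synthetic.default_chromosomes()
    genome_bp = sum(c.length for c in chroms)
    plans = synthetic.default_plans(genome_bp)
    te = synthetic.load_te_library()
    genome, truth = synthetic.plant_genome(chroms, plans, seed=11, te_library=te)
    pairs = synthetic.simulate_reads(genome, 1.2, 151, 350, 0.002, seed=12)
    cfg = mining.MiningConfig(min_cluster_size=10)
    monomers, rounds = mining.run_satminer(pairs, n_rounds=3, seed=13, cfg=cfg)
    landscapes, total_bp = landscape_mod.compute_landscapes(
        {m.name: m.sequence for m in monomers}, pairs, seed=14
    )
    return {"chromosomes": chroms, "plans": plans, "genome": genome, "truth": truth,
            "pairs": pairs, "monomers": monomers, "rounds": rounds,
            "landscapes": landscapes, "total_read_bp": total_bp, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
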