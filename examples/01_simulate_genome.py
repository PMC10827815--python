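"""Plant satDNA families in a synthetic genome and simulate paired reads.

Builds a 1 Mb two-chromosome genome carrying two tandem-repeat families of
known unit, copy number and amplification age, then simulates 1.2x paired-end
reads. The printed numbers are the ground truth every later stage is scored
against: planted genome proportion and the realized unit-to-consensus
divergence (which should sit near the requested mutation age).
"""

from satkit import synthetic

chromosomes = [
    synthetic.ChromosomeSpec("chr1", 600_000, 250_000),
    synthetic.ChromosomeSpec("chr2", 400_000, 180_000),
]
plans = [
    synthetic.FamilyPlan("DemoSat01", unit_length=300, at_target=0.6,
                         n_units_clustered=60, array_loci=[("chr1", "terminal")],
                         mutation_age=0.03),
    synthetic.FamilyPlan("DemoSat02", unit_length=150, at_target=0.45,
                         n_units_clustered=80, array_loci=[("chr2", "pericentromeric")],
                         mutation_age=0.08),
]
genome, truth = synthetic.plant_genome(chromosomes, plans, seed=1)
pairs = synthetic.simulate_reads(genome, coverage=1.2, read_length=151,
                                 insert_mean=350, error_rate=0.002, seed=2)

print(f"genome: {sum(len(s) for s in genome.values()):,} bp, "
      f"{len(pairs):,} read pairs at 1.2x")
for plan in plans:
    gp = truth.genome_proportion[plan.name]
    div = truth.mean_divergence[plan.name]
    print(f"{plan.name}: planted {truth.planted_bp(plan.name):,} bp "
          f"({gp * 100:.3f}% of genome), realized divergence {div * 100:.2f}% "
          f"(age requested {plan.mutation_age * 100:.0f}%)")
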