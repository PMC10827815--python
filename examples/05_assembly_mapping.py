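"""Map satDNA families onto an assembly and classify their distribution.

Plants one family per chromosomal distribution class (terminal,
(peri)centromeric, mixed major loci, dispersed short tandems), searches the
assembly with each consensus (seed-and-extend), merges unit hits into tandem
arrays and calls the FISH-style distribution class - which should recover
the planted class for every family. Also reports telomere-motif presence in
the terminal windows.
"""

from satkit import compare_map, synthetic

chroms, plans = synthetic.default_distribution_plans()
genome, truth = synthetic.plant_genome(chroms, plans, seed=21)

hits_by_family = {}
for plan in plans:
    cons = truth.consensus[plan.name]
    hits = compare_map.search_assembly(cons, genome)
    arrays = compare_map.merge_hits_to_arrays(hits, len(cons))
    call = compare_map.classify_distribution(plan.name, arrays, chroms)
    hits_by_family[plan.name] = hits
    major = [a for a in arrays if a.n_units >= 5]
    print(f"{plan.name}: {len(hits)} unit hits -> {len(arrays)} arrays "
          f"({len(major)} major) -> class '{call.label}'")

window = compare_map.terminal_window_size(chroms[0].length)
table = compare_map.scan_terminal_windows(genome, window, hits_by_family)
telomeres = sum(table[c][side]["telomere"] for c in genome for side in ("left", "right"))
print(f"telomere motif (TTTAGGG)n present at {telomeres}/{2 * len(genome)} "
      f"chromosome ends; terminal window {window:,} bp")
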