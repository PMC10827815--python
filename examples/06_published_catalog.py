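"""Summary statistics of the published bread-wheat satellitome catalog.

Loads the 34-family catalog shipped with the package and recomputes the
study's headline numbers from its columns alone: total satellitome size,
abundance/length/composition counts, superfamilies, and how many families
were new relative to the 13 previously described wheat satellites.
"""

from satkit import report

records = report.records_from_dataframe(report.load_published_catalog())
s = report.summarize(records, genome_size_mbp=16_954, known_families=13)

print(f"families: {s.n_families}")
print(f"total abundance: {s.total_abundance_pct:.2f}% of the genome "
      f"= {s.satellitome_mbp:.0f} Mbp at {s.genome_size_mbp:,.0f} Mbp")
print(f"abundant (>0.05%): {s.n_abundant}; scarce (<0.01%): {s.n_scarce}")
print(f"unit <100 bp: {s.n_short}; unit >1 kb: {s.n_long}; AT-rich: {s.n_at_rich}")
print(f"superfamilies: {s.n_superfamilies}")
print(f"divergence range: {s.min_divergence_pct:.2f}-{s.max_divergence_pct:.2f}%")
print(f"total copies: {s.total_copies:,}; new families: {s.n_new_families}")
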