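"""Structural characterization of a consensus monomer.

Builds a 620-bp monomer as four diverged copies of a 155-bp subunit (the
footprint of past unit-length amplification) and reports the full battery:
AT content, internal direct subrepeats, inverted repeats / dyad symmetries,
the best nearest-neighbor hairpin free energy, and the curvature-propensity
profile with its low/curved classification.
"""

from satkit import monomer, synthetic

plan = synthetic.FamilyPlan("DemoSat", 620, at_target=0.62, subrepeat_period=155)
seq = synthetic.build_monomer(plan, seed=9)
report = monomer.structure_report("DemoSat", seq)

print(f"AT content: {report.at_percent:.1f}%")
best = report.subrepeats[0]
print(f"direct subrepeat: period {best.period} bp x {best.copies} copies "
      f"at {best.identity * 100:.0f}% identity "
      f"({best.fraction_of_monomer * 100:.0f}% of the unit explained)")
long_irs = [ir for ir in report.inverted_repeats if ir.stem >= 10]
print(f"inverted repeats: {len(report.inverted_repeats)} total, "
      f"{len(long_irs)} dyads with stems >= 10 bp")
if report.hairpin:
    h = report.hairpin
    print(f"best hairpin: stem {h.stem} bp, loop {h.loop} nt, "
          f"dG = {h.dg:.2f} kcal/mol (more negative = more stable)")
print(f"curvature peak: {report.curvature.peak_value:.1f} deg/10.5-bp turn "
      f"-> classified '{report.curvature_class}' (threshold 14)")
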