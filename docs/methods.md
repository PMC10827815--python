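# Methods

This note records the models, estimators and numerical choices behind
`satkit`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## The synthetic study and what it emulates

The generator plants satDNA families into an i.i.d. background genome
(configurable GC, default 46%) as head-to-tail tandem arrays at terminal,
pericentromeric or interstitial positions, plus optional dispersed 1-3-unit
tandems; every chromosome carries (TTTAGGG)n telomere caps. Coordinates are
0-based half-open throughout.

**Monomer construction.** De novo monomers are drawn with an exact AT count
(round(at x L) A/T bases, shuffled): composition is a reported catalog
column, and the i.i.d. sampler's binomial scatter would miss short units by
several percent. A family may instead be derived from an ancestor (mutated
copy, truncated/padded to its unit length - this plants superfamily
relatedness), built as a tandem of a shorter subunit with per-copy
divergence (default 10% - plants internal direct subrepeats), and/or carry a
segment copied from a TE consensus library. The shipped TE library
(`satkit/data/te_library_synthetic.fa`) is a synthetic stand-in generated
once with a fixed seed; real TE consensus databases are not redistributable.

**Mutation model.** Substitutions only, with a 2:1 transition:transversion
ratio (so K2P genuinely differs from the p-distance) and sequential events
that allow multiple hits. The generic mutator draws a Poisson(age) event
count per site. When *planting arrays*, each unit instead receives a fixed
load of round(age x L) events at uniform positions: units born of one
amplification event and homogenized by concerted evolution share a
near-common divergence, and this convention is what makes the landscape peak
(DIVPEAK) a sharp, recoverable one-bin statistic. The per-unit Poisson
alternative adds sqrt(age x L)/L of between-unit scatter, which flattens the
histogram top at high ages.

**Reads.** Uniform fragment starts, normal insert length (sd = 10% of the
mean), mates on opposite strands, flat qualities, substitution errors at a
flat rate (default 0.2%, a high-quality short-read regime), total read bp =
coverage x genome bp to rounding. Defaults mirror the study regime at desk
scale: 151 bp reads at 1.2x coverage. Not modelled: quality profiles, PCR
duplicates, indel errors, structural variation, GC bias.

**Default catalog.** Ten families spanning 0.005-0.5% of a 5 Mb genome,
unit lengths 44-1500 bp, AT 36-70%, amplification ages cycling through
2% / 7% / 12%, one subunit-built family (620 = 4 x 155), one TE-derived
family, one ancestor-derived pair (planted superfamily), and two rare
families (0.012% and 0.005%) that sit *below* the detection floor of the
read-clustering stage by design - at 1.2x coverage they contribute only a
handful of reads. Layout choices that matter:

- each age tier is led by a family of >= 50 units whose unit is at most one
  read length, so a read carries the almost exact per-unit substitution
  load and the landscape peak is sharp (window-sampling noise over long
  units spreads the peak by +/-2 bins or more);
- the 1.5 kb family sits at 0.26% of the genome (~9 units): a long unit at
  5 copies would leave e^(-6) x 1500 ~ 4 consensus positions with zero read
  coverage at 1.2x, physically breaking the cycle no algorithm could close.

## Mining

Round structure: sample read pairs -> similarity graph -> connected
components -> circularity -> consensus -> filter library -> repeat. Mates
are clustered as independent sequences; pair linkage is used only when
filtering (both mates go if either matches).

**Similarity graph.** Candidate read pairs share >= 5 canonical k-mers
(k = 13); candidates are confirmed at >= 80% alignment identity, first by
end-to-end edit identity (edlib), then by a local-alignment score screen
(+1/-1, affine gaps) that absorbs the phase shifts of reads drawn from
different offsets of a tandem. The candidate word is 13 nt rather than the
natural 21 because an exact 21-mer survives two ~10%-diverged unit copies
with probability 0.88^21 ~ 0.01: at 21 the filter never proposes pairs
between units of an aged family and such families are undiscoverable.
Edge confirmation stops once a read has 8 confirmed neighbours - components,
not complete cliques, are what clustering needs - which keeps graph
construction near-linear in satellite cluster size.

**Circularity.** A cluster's tandem signature is a cycle dominating its de
Bruijn graph. The score is the fraction of cluster read bp aligning (>= 70%
identity) to a tandem of the best cycle; a cluster with no cycle (a
single-copy locus tiles into a path) scores 0. Scoring by read support
rather than by on-cycle k-mer weight matters for the same reason as the
candidate word size: a 10%-diverged unit shares almost no exact 21-mers
with its consensus yet aligns to it readily, so the raw weight fraction
decays with intra-family divergence and would reject every aged family at
the 0.5 threshold. The raw statistic remains available as
`cycle_weight_fraction`.

**Consensus extraction.** Cycle candidates are produced at a ladder of word
sizes (41, 31, 21, 13; long to short) by two extractors: an exact
maximum-mean-weight cycle (Karp's algorithm on the pruned graph, vectorized
DP; verified against brute-force cycle enumeration on toy graphs) and a
greedy majority walk with backtracking on the unpruned graph (follows the
locally heaviest arc; closes when the heaviest arc re-enters the walk). Long
words keep internally subrepeated monomers from short-circuiting onto their
subunit cycle; short words keep the consensus cycle of an aged family
unbroken. Every candidate is scored by aligning the cluster reads back to
it; the candidate with the best mean read identity (then aligned fraction,
then length) wins, and the ladder stops early only for a clean
(mean identity >= 0.90, support >= 0.5) cycle at a long word.

Accepted cycles must pass two anti-artifact gates: cycle coverage (aligned
cluster bp / cycle length >= 3 - a genuine satellite tandems through its
cluster several times, while a chance "lasso" cycle closing a unique,
locally over-sampled genomic segment is covered ~1x) and tandem-junction
support (>= 2 reads matching >= 70% on both sides of a monomer boundary over
>= 35 bp - lasso reads run linearly past the closing repeat and fail on the
far side).

The consensus is polished by per-position majority vote of the cluster reads
(substitution-only, so the unit length is preserved), then checked for
multimer collapse: if the polished consensus tandems a shorter subunit at
>= 80% identity over >= 95% of its length, and the polished subunit explains
the reads essentially as well (within 0.01 mean identity), the shortest such
period is reported. After polishing, a dimer produced by a shared word
between neighbouring diverged units ties with its fundamental period,
whereas a genuine long monomer with internal subrepeats wins against any
single subunit by a wide margin. Consensus sequences are reported in
canonical rotation (lexicographically minimal over both strands).

Families are deduplicated at >= 95% rotational identity; filtering removes a
read pair when either mate matches any known monomer (doubled, both
strands) at >= 80% identity over >= 50% of its length, with an 11-mer probe
prefilter for speed. The minimum cluster size is 10 reads at desk scale
(~20k read pairs per round); the reference-scale value of 25 corresponds to
2M-read samples and scales with library size.

## Landscapes

Reads are assigned to the single best-matching monomer (as a masking screen
would, so related families do not double-count nucleotides), aligned against
the doubled monomer on both strands to absorb rotations and tandem
junctions. Segment location uses edlib; substitutions are then recounted
from an affine-gap realignment (match +1, mismatch -1, open -4, extend -1):
unit-cost edit distance happily rewrites substitutions as indel pairs,
which - with indel columns rightly excluded from a substitution model -
deflates divergence by ~15% at age 12%. Indel columns are excluded from both
the substitution counts and the aligned-bp mass. Segments need >= 50 matched
columns at >= 65% identity.

Each segment's aligned bp accrues to bin floor(100 x K), K2P computed from
its transition/transversion fractions; bins are 1% wide over 0-70%
(saturated segments are skipped). DIVPEAK is the argmax bin (ties toward
lower divergence), PEAK-SIZE sums bins within +/-2 of DIVPEAK (clipped at
0), RPS = 100 x PEAK-SIZE / total abundance. The per-family mean divergence
reported in catalogs is the abundance-weighted mean over bin midpoints
(whether the original tabulations used the weighted mean or the histogram
median is not stated anywhere; the weighted mean matches the landscape's
abundance weighting and is labelled as such). CpG-adjusted K2P is not
applied.

Sampling floors: DIVPEAK/RPS are read on families with >= 50 planted units,
and genome proportions are compared to truth only for families with
>= 10 kb planted (~80 reads at 1.2x), where the +/-50% relative band is at
least ~3 sigma of the clustered (paired-read) sampling noise. Rarer
families are scored as detected-or-not.

## Monomer structure

The monomer is treated as circular everywhere: satDNA units are tandem and
the consensus phase is arbitrary.

- **Direct subrepeats**: every period p in [min_period, L/2] is scored by
  circular column-consensus identity over floor(L/p) copies; qualifying
  periods (identity >= 0.6, >= 2 copies) that are near-multiples of a
  smaller qualifying period are suppressed. Verified equivalent to an
  independent brute-force period scan on hundreds of short sequences.
- **Inverted repeats**: maximal stems >= 5 bp with loops <= 100 and 0
  mismatches by default, center extension; hits nested inside a longer hit
  are suppressed. Verified against brute-force arm-pair enumeration.
- **Hairpin dG**: perfect-stem hairpins only (loops 3-30 nt), scored with
  unified nearest-neighbor dG37 stack parameters plus a tabulated hairpin
  loop penalty (linear interpolation; Jacobson-Stockmayer extrapolation
  beyond 30 nt); the minimum over all stems is reported. This is an
  explicit simplification of full minimum-free-energy folding - no
  multiloops, bulges, dangles or salt correction - intended as a
  comparative stability index, which is how the dG column is used. Only the
  37 degC table is embedded.
- **Curvature**: per-position trinucleotide propensity, triangular smoothing
  over a 31-bp window on the circular monomer, scaled to degrees per
  10.5-bp helical turn. The embedded DNase-I bendability values are the
  commonly transcribed 32-trinucleotide set; the curvature scale applied to
  them is a package-defined monotone transform (min-max inversion:
  rigid A-tract-like triplets map high, flexible G/C-rich ones low) with a
  fixed calibration of 10 degrees per unit propensity, chosen so that a
  G homopolymer sits well below 5 degrees and phased A-tracts score
  clearly above it. It preserves the orderings the analysis relies on, not
  server-exact magnitudes. The low/curved classification threshold is a
  strict > 14 degrees/10.5 bp.

## Comparison and mapping

Monomer pairs are aligned rotation- and strand-aware (query vs doubled
target, best local block). Superfamilies are single-linkage components over
links with >= 65% identity covering >= 25% of the shorter monomer *and* a
local score >= 30: the score floor plays the role of a complexity-adjusted
cutoff, since the empirical random-sequence null tops out near score 23 and
chance low-identity blocks between short monomers would otherwise forge
links. The same floor guards the TE-homology screen (reported: coverage %
of the monomer, identity, class). The 25% aligned-fraction default reflects
superfamilies whose members retain identity only in part of the unit.

Assembly search is seed-and-extend: exact 13-mer seeds per strand anchor
candidate regions, which are tiled by repeated end-gap-free alignments of
the monomer so tandem arrays decompose into unit-scale hits (>= 70%
identity over >= half the unit; minus-strand hits on forward coordinates).
Same-strand hits with gaps <= 0.2 x unit merge into arrays
(n_units = round(length/unit), floored at 1; merging is idempotent). A
"major locus" - the in-silico analogue of a FISH-visible band - is an array
of >= 5 units (the size at which cytogenetic visibility is contrasted with
short tandems in the literature, which gives no numeric bound; the
threshold is configurable and recorded in outputs). Distribution classes:
Terminal if all major loci fall in distal windows (min(500 kb, 5% of the
chromosome); the 500 kb convention capped for desk-scale chromosomes),
(peri)centromeric if all fall within +/-5% of chromosome length around the
centromere (no numeric bound exists in the source tabulations; declared,
configurable), Dispersed if there is no major locus but >= 50 minor loci
over >= half the chromosomes, "absent" with no hits, otherwise Multiple
locations. Telomere calls require >= 3 consecutive TTTAGGG (strand
appropriate) within the terminal 1 kb.

## Catalog and summary

Families are named `<prefix>NN-<len>` ordered by descending abundance; total
bp = genome proportion x the stated sequence basis; copies = total bp / unit
length rounded half-up. The shipped published-catalog fixture normalizes
decimal commas and stores the divergence column as percent; its checksum is
recorded in run manifests. Summary counts use strict inequalities
(abundance > 0.05%, < 0.01%; AT > 50%; unit < 100, > 1000 bp). The fixture's
copies column sums to 1,367,988 (one more than its printed total row, an
arithmetic slip in the source table; the summary reports the column sum).
Pearson correlations come with two-sided t-test p-values; zero-variance
input yields NaN.

## Determinism and problem sizes

Every stochastic step is a pure function of its seed; whole-pipeline outputs
are byte-identical across re-runs. The default study sizes - 5 Mb genome,
~20k read pairs, 3 mining rounds, full-library landscape - run the complete
pipeline in a few minutes on one core and were chosen as the smallest scale
at which all planted effects are statistically resolvable; everything is
configurable upward.

## Known limitations

- Clustering is connected components over a thresholded overlap graph, not
  the reference tool's community detection; very similar families sharing
  >= 80%-identity reads can co-cluster (they are separated downstream by
  deduplication and landscape assignment).
- The circularity score and consensus extraction assume one dominant tandem
  per cluster; adversarial co-clustered monomers yield the best-supported
  cycle and flag the cluster low-confidence.
- Hairpin dG underestimates stability relative to full folding (no
  multiloops/bulges) and curvature magnitudes are calibrated, not
  server-exact (orderings and the threshold behaviour are what tests pin).
- The read simulator's flat error/quality model makes mining slightly
  easier than real data; passing recovery tests here demonstrates method
  correctness under the stated model, not performance on instrument
  artifacts.
- Genome-proportion estimates inherit clustered (paired-read) sampling
  noise; for families below ~80 expected reads the +/-50% band is not
  statistically meaningful and such families are scored as detected or not.
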