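"""Synthetic genomes with planted satDNA families and simulated paired reads.

This module is the test bed for the whole pipeline: it plants tandem-repeat
families with known unit sequence, copy number, chromosomal organization and
"amplification age" (expected substitutions per site since the last
amplification event), writes the ground truth alongside, and simulates
error-bearing paired-end reads, so that mining, landscape and mapping stages
can be scored against a known answer.

Design notes
------------
* The background genome is i.i.d. uniform ACGT at a configurable GC content;
  tandem-repeat detection does not require linguistic structure.
* The mutation model is substitutions only, applied as a Poisson number of
  events per site with a 2:1 transition:transversion ratio, so that Kimura
  2-parameter distances differ from raw p-distances and multiple hits are
  possible (the landscape stage must invert them).
* Telomeres are (TTTAGGG)n caps on the forward strand at the left end and
  their reverse complement at the right end.
* All coordinates are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._alignment import revcomp

TELOMERE_MOTIF = "TTTAGGG"
BASES = np.array(list("ACGT"))
#: transition partner of each base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

PLACEMENT_CLASSES = ("terminal", "pericentromeric", "interstitial")


class ConfigurationError(ValueError):
    """Raised for invalid family plans or unknown ancestor / TE references."""


class PlacementError(RuntimeError):
    """Raised when a planted locus cannot be placed without collision."""


@dataclass
class FamilyPlan:
    """Blueprint for one planted satDNA family."""

    name: str
    unit_length: int
    at_target: float = 0.55
    n_units_clustered: int = 0
    array_loci: list[tuple[str, str]] = field(default_factory=list)
    n_dispersed_units: int = 0
    mutation_age: float = 0.0
    ancestor: str | None = None
    ancestor_divergence: float = 0.30
    te_fragment: tuple[str, float] | None = None
    subrepeat_period: int | None = None
    subrepeat_divergence: float = 0.10

    def __post_init__(self):
        if self.unit_length < 10:
            raise ConfigurationError(f"{self.name}: unit_length must be >= 10")
        if not 0.0 <= self.at_target <= 1.0:
            raise ConfigurationError(f"{self.name}: at_target must be in [0, 1]")
        if self.mutation_age < 0:
            raise ConfigurationError(f"{self.name}: mutation_age must be >= 0")
        if self.subrepeat_period is not None:
            p = self.subrepeat_period
            if p <= 0 or self.unit_length % p != 0 or self.unit_length // p < 2:
                raise ConfigurationError(
                    f"{self.name}: subrepeat_period must divide unit_length >= 2 times"
                )
        for _, cls in self.array_loci:
            if cls not in PLACEMENT_CLASSES:
                raise ConfigurationError(f"{self.name}: unknown placement class {cls!r}")


@dataclass
class ChromosomeSpec:
    """A synthetic chromosome: length, centromere offset and telomere cap size."""

    name: str
    length: int
    centromere_position: int
    telomere_repeats: int = 30

    def __post_init__(self):
        if not 0 < self.centromere_position < self.length:
            raise ConfigurationError(f"{self.name}: centromere must lie inside the chromosome")


@dataclass
class PlacedInterval:
    chromosome: str
    start: int
    end: int
    n_units: int
    strand: str


@dataclass
class SyntheticTruth:
    """The planting plan as realized: where every family ended up, and how diverged."""

    intervals: dict[str, list[PlacedInterval]]
    consensus: dict[str, str]
    genome_proportion: dict[str, float]
    mean_divergence: dict[str, float]
    genome_bp: int

    def planted_bp(self, family: str) -> int:
        return sum(iv.end - iv.start for iv in self.intervals[family])

    def to_bed(self, path) -> None:
        """BED6: name = family, score = number of units."""
        with open(path, "w") as fh:
            for fam, ivs in self.intervals.items():
                for iv in ivs:
                    fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{fam}\t{iv.n_units}\t{iv.strand}\n")

    def to_json(self, path) -> None:
        payload = {
            "genome_bp": self.genome_bp,
            "consensus": self.consensus,
            "genome_proportion": self.genome_proportion,
            "mean_divergence": self.mean_divergence,
            "intervals": {
                fam: [dataclasses.asdict(iv) for iv in ivs] for fam, ivs in self.intervals.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(n: int, rng: np.random.Generator, at: float = 0.5) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _random_seq_exact_at(n: int, rng: np.random.Generator, at: float) -> str:
    """Random sequence whose AT fraction hits the target to rounding.

    Used for monomers, whose composition is a reported catalog column; the
    i.i.d. sampler's binomial scatter would miss short units by several
    percent.
    """
    n_at = int(round(at * n))
    bases = ["AT"[rng.integers(2)] for _ in range(n_at)]
    bases += ["CG"[rng.integers(2)] for _ in range(n - n_at)]
    perm = rng.permutation(n)
    return "".join(bases[i] for i in perm)


def mutate_sequence(seq: str, age: float, rng: np.random.Generator,
                    n_events: int | None = None) -> str:
    """Apply an expected *age* substitutions per site to *seq*.

    By default events per site are Poisson(age); passing ``n_events`` fixes
    the total substitution load instead (events land on uniform positions,
    multiple hits possible) - the convention used when planting tandem
    arrays, where concerted evolution keeps the units of one amplification
    event at a near-common divergence rather than independently scattered.
    Each event is a transition with probability 2/3 (2:1 ts:tv).
    """
    if age <= 0 and not n_events:
        return seq
    if n_events is None:
        per_site = rng.poisson(age, size=len(seq))
    else:
        per_site = np.bincount(rng.integers(0, len(seq), size=n_events),
                               minlength=len(seq))
    if not per_site.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(per_site):
        b = out[i]
        for _ in range(per_site[i]):
            if b == "N":
                break
            if rng.random() < 2.0 / 3.0:
                b = _TRANSITION[b]
            else:
                b = _TRANSVERSIONS[b][rng.integers(2)]
        out[i] = b
    return "".join(out)


def build_monomer(plan: FamilyPlan, seed: int, monomers: dict[str, str] | None = None,
                  te_library: dict[str, str] | None = None) -> str:
    """Construct the consensus monomer sequence for *plan*.

    ``monomers`` supplies already-built ancestor monomers for superfamily
    relatedness; ``te_library`` supplies TE consensus sequences for planted
    TE-derived segments. The AT-content target applies to de novo generated
    sequence (inherited ancestor/TE segments keep their own composition).
    """
    rng = np.random.default_rng(seed)
    L = plan.unit_length
    if plan.ancestor is not None:
        if not monomers or plan.ancestor not in monomers:
            raise ConfigurationError(f"{plan.name}: unknown ancestor {plan.ancestor!r}")
        base = mutate_sequence(monomers[plan.ancestor], plan.ancestor_divergence, rng)
        if len(base) >= L:
            seq = base[:L]
        else:
            seq = base + _random_seq_exact_at(L - len(base), rng, plan.at_target)
    elif plan.subrepeat_period is not None:
        p = plan.subrepeat_period
        subunit = _random_seq_exact_at(p, rng, plan.at_target)
        seq = "".join(
            mutate_sequence(subunit, plan.subrepeat_divergence, rng) for _ in range(L // p)
        )
    else:
        seq = _random_seq_exact_at(L, rng, plan.at_target)
    if plan.te_fragment is not None:
        te_name, fraction = plan.te_fragment
        if not te_library or te_name not in te_library:
            raise ConfigurationError(f"{plan.name}: unknown TE {te_name!r}")
        te_seq = te_library[te_name]
        n = min(int(round(fraction * L)), L, len(te_seq))
        start = int(rng.integers(0, max(1, len(te_seq) - n + 1)))
        seq = te_seq[start:start + n] + seq[n:]
    return seq[:L]


def _terminal_window(chrom: ChromosomeSpec) -> int:
    """Distal window size: 500 kb or 5% of the (shorter) arm, whichever is smaller."""
    arm = min(chrom.centromere_position, chrom.length - chrom.centromere_position)
    return min(500_000, max(1, int(0.05 * arm)))


class _Occupancy:
    """Per-chromosome interval bookkeeping with collision rejection."""

    def __init__(self):
        self.taken: list[tuple[int, int]] = []

    def fits(self, start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in self.taken)

    def add(self, start: int, end: int) -> None:
        self.taken.append((start, end))


def _pick_position(chrom: ChromosomeSpec, cls: str, size: int, occ: _Occupancy,
                   rng: np.random.Generator, retries: int = 200) -> int:
    tel = chrom.telomere_repeats * len(TELOMERE_MOTIF)
    L = chrom.length
    w = _terminal_window(chrom)
    cen_half = max(1, int(0.05 * L))
    for _ in range(retries):
        if cls == "terminal":
            if rng.random() < 0.5:
                lo, hi = tel, max(tel + 1, tel + w - size)
            else:
                lo, hi = max(tel, L - tel - w), max(tel + 1, L - tel - size)
        elif cls == "pericentromeric":
            lo = max(tel, chrom.centromere_position - cen_half)
            hi = min(L - tel - size, chrom.centromere_position + cen_half - size)
        else:  # interstitial or dispersed placement
            lo, hi = tel + w, L - tel - w - size
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        if cls == "interstitial":
            # stay clear of the pericentromere so the class label is unambiguous
            if abs(start + size // 2 - chrom.centromere_position) < cen_half + size:
                continue
        if occ.fits(start, start + size):
            return start
    raise PlacementError(f"could not place a {size} bp locus on {chrom.name}")


def plant_genome(chromosomes: list[ChromosomeSpec], plans: list[FamilyPlan], seed: int,
                 gc: float = 0.46, te_library: dict[str, str] | None = None):
    """Build genome sequences with planted families; return (genome, truth).

    Clustered loci are head-to-tail tandems of >= 5 units, each unit
    independently mutated at the family's amplification age; dispersed units
    go down singly or in tandems of 1-3 at uniform positions. Both ends of
    every chromosome carry the telomere cap.
    """
    rng = np.random.default_rng(seed)
    total_bp = sum(c.length for c in chromosomes)
    planned_bp = sum(
        p.unit_length * (p.n_units_clustered + p.n_dispersed_units) for p in plans
    )
    if planned_bp >= 0.5 * total_bp:
        raise ConfigurationError("planted satDNA would exceed 50% of the genome")

    # ancestors first so derived plans can see them
    monomers: dict[str, str] = {}
    pending = list(plans)
    while pending:
        progressed = False
        for plan in list(pending):
            if plan.ancestor is None or plan.ancestor in monomers:
                monomers[plan.name] = build_monomer(
                    plan, int(rng.integers(2**31)), monomers, te_library
                )
                pending.remove(plan)
                progressed = True
        if not progressed:
            missing = ", ".join(p.ancestor or "?" for p in pending)
            raise ConfigurationError(f"unresolvable ancestor reference(s): {missing}")

    genome: dict[str, np.ndarray] = {}
    occupancy: dict[str, _Occupancy] = {}
    chrom_by_name = {c.name: c for c in chromosomes}
    for c in chromosomes:
        arr = np.frombuffer(_random_seq(c.length, rng, 1 - gc).encode(), dtype="S1").copy()
        cap = (TELOMERE_MOTIF * c.telomere_repeats).encode()
        arr[: len(cap)] = np.frombuffer(cap, dtype="S1")
        rcap = revcomp(TELOMERE_MOTIF * c.telomere_repeats).encode()
        arr[len(arr) - len(rcap):] = np.frombuffer(rcap, dtype="S1")
        genome[c.name] = arr
        occ = _Occupancy()
        tel = c.telomere_repeats * len(TELOMERE_MOTIF)
        occ.add(0, tel)
        occ.add(c.length - tel, c.length)
        occupancy[c.name] = occ

    truth_ivs: dict[str, list[PlacedInterval]] = {p.name: [] for p in plans}
    div_sums: dict[str, list[float]] = {p.name: [] for p in plans}

    def _place_tandem(plan: FamilyPlan, chrom_name: str, cls: str, n_units: int):
        chrom = chrom_by_name[chrom_name]
        units = []
        load = int(round(plan.mutation_age * plan.unit_length))
        for _ in range(n_units):
            unit = mutate_sequence(monomers[plan.name], plan.mutation_age, rng,
                                   n_events=load)
            units.append(unit)
            mism = sum(a != b for a, b in zip(unit, monomers[plan.name]))
            div_sums[plan.name].append(mism / plan.unit_length)
        array = "".join(units)
        strand = "+"
        if rng.random() < 0.5:
            array = revcomp(array)
            strand = "-"
        start = _pick_position(chrom, cls, len(array), occupancy[chrom_name], rng)
        occupancy[chrom_name].add(start, start + len(array))
        genome[chrom_name][start:start + len(array)] = np.frombuffer(array.encode(), dtype="S1")
        truth_ivs[plan.name].append(
            PlacedInterval(chrom_name, start, start + len(array), n_units, strand)
        )

    for plan in plans:
        if plan.n_units_clustered:
            if not plan.array_loci:
                raise ConfigurationError(f"{plan.name}: clustered units but no array loci")
            k = len(plan.array_loci)
            per = [plan.n_units_clustered // k] * k
            for i in range(plan.n_units_clustered % k):
                per[i] += 1
            if min(per) < 5:
                raise ConfigurationError(
                    f"{plan.name}: clustered loci must hold >= 5 units each"
                )
            for (chrom_name, cls), n_units in zip(plan.array_loci, per):
                _place_tandem(plan, chrom_name, cls, n_units)
        remaining = plan.n_dispersed_units
        while remaining > 0:
            n = int(min(remaining, rng.integers(1, 4)))
            chrom = chromosomes[int(rng.integers(len(chromosomes)))]
            _place_tandem(plan, chrom.name, "interstitial", n)
            remaining -= n

    truth = SyntheticTruth(
        intervals=truth_ivs,
        consensus=monomers,
        genome_proportion={
            p.name: sum(iv.end - iv.start for iv in truth_ivs[p.name]) / total_bp for p in plans
        },
        mean_divergence={
            p.name: float(np.mean(div_sums[p.name])) if div_sums[p.name] else 0.0 for p in plans
        },
        genome_bp=total_bp,
    )
    return {name: arr.tobytes().decode() for name, arr in genome.items()}, truth


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str


def simulate_reads(genome: dict[str, str], coverage: float, read_length: int = 151,
                   insert_mean: int = 350, error_rate: float = 0.002,
                   seed: int = 0) -> list[ReadPair]:
    """Uniform paired-end read simulation with substitution errors.

    Total read bp is coverage x genome bp (to rounding); mates sit on opposite
    strands of a fragment whose length is normal around ``insert_mean``.
    """
    if coverage <= 0:
        raise ConfigurationError("coverage must be > 0")
    shortest = min(len(s) for s in genome.values())
    if not read_length <= insert_mean <= shortest:
        raise ConfigurationError("need read_length <= insert_mean <= shortest chromosome")
    rng = np.random.default_rng(seed)
    names = sorted(genome)
    lengths = np.array([len(genome[n]) for n in names], dtype=float)
    total = int(lengths.sum())
    n_pairs = int(round(coverage * total / (2 * read_length)))
    chrom_idx = rng.choice(len(names), size=n_pairs, p=lengths / lengths.sum())
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, 0.1 * insert_mean, size=n_pairs)).astype(int),
        read_length,
        int(lengths.min()),
    )
    flips = rng.random(n_pairs) < 0.5
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        chrom = names[chrom_idx[i]]
        seq = genome[chrom]
        ins = int(inserts[i])
        start = int(rng.integers(0, len(seq) - ins + 1))
        frag = seq[start:start + ins]
        r1, r2 = frag[:read_length], revcomp(frag[-read_length:])
        if flips[i]:
            r1, r2 = r2, r1
        pairs.append(ReadPair(f"sim_{i}:{chrom}:{start}", r1, r2))
    if error_rate > 0:
        for pair in pairs:
            pair.seq1 = _add_errors(pair.seq1, error_rate, rng)
            pair.seq2 = _add_errors(pair.seq2, error_rate, rng)
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for i in pos:
        alt = "ACGT".replace(out[i], "") if out[i] in "ACGT" else "ACGT"
        out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_fastq_pair(pairs: list[ReadPair], prefix) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq`` (flat qualities)."""
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            q1 = "I" * len(pair.seq1)
            q2 = "I" * len(pair.seq2)
            f1.write(f"@{pair.name}/1\n{pair.seq1}\n+\n{q1}\n")
            f2.write(f"@{pair.name}/2\n{pair.seq2}\n+\n{q2}\n")
    return p1, p2


def read_fastq_pair(path1, path2) -> list[ReadPair]:
    from Bio import SeqIO

    pairs = []
    for r1, r2 in zip(SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")):
        pairs.append(ReadPair(r1.id.rsplit("/", 1)[0], str(r1.seq).upper(), str(r2.seq).upper()))
    return pairs


# ---------------------------------------------------------------------------
# Default desk-scale study conditions
# ---------------------------------------------------------------------------

def default_chromosomes(genome_mb: float = 5.0, n_chromosomes: int = 4) -> list[ChromosomeSpec]:
    """Equal-sized chromosomes with submetacentric centromeres and telomere caps."""
    length = int(genome_mb * 1e6 / n_chromosomes)
    return [
        ChromosomeSpec(f"chr{i + 1}", length, int(0.45 * length), telomere_repeats=30)
        for i in range(n_chromosomes)
    ]


def default_plans(genome_bp: int = 5_000_000) -> list[FamilyPlan]:
    """The default 10-family synthetic catalog.

    Abundances span 0.005-0.5% of the genome with two deliberately rare
    families below the read-cluster detection floor at 1.2x coverage; unit
    lengths span 44-1500 bp; amplification ages cycle through three levels
    (2%, 7%, 12%) so that landscape indices can be scored against age; one
    family is built from a 155-bp subunit, one is TE-derived and one pair
    shares superfamily ancestry.
    """
    spec = [
        # name, unit, AT, abundance (% genome), age, loci classes. The three
        # age tiers each lead with a well-populated (>= 50 units) family
        # whose unit is at most one read length: such reads carry the almost
        # exact per-unit substitution load, which keeps the landscape peak
        # sharp enough for DIVPEAK to be a meaningful one-bin statistic.
        ("SynFam01", 150, 0.37, 0.50, 0.02, [("chr1", "terminal"), ("chr2", "terminal")]),
        ("SynFam02", 130, 0.60, 0.41, 0.07, [("chr1", "pericentromeric"), ("chr3", "pericentromeric")]),
        ("SynFam03", 100, 0.59, 0.33, 0.12, [("chr2", "interstitial")]),
        # the 1.5 kb family sits at 0.26% so its consensus circle is fully
        # tiled by reads (a long unit at low copy number leaves physical
        # coverage gaps at 1.2x and cannot be reconstructed by any method)
        ("SynFam04", 1500, 0.36, 0.26, 0.02, [("chr4", "pericentromeric")]),
        ("SynFam05", 620, 0.63, 0.20, 0.02, [("chr4", "interstitial")]),
        ("SynFam06", 584, 0.65, 0.15, 0.07, [("chr3", "terminal")]),
        ("SynFam07", 337, 0.57, 0.11, 0.12, [("chr2", "terminal")]),
        ("SynFam08", 210, 0.48, 0.08, 0.07, [("chr3", "interstitial")]),
        ("SynFam09", 72, 0.50, 0.012, 0.12, [("chr1", "interstitial")]),
        ("SynFam10", 44, 0.70, 0.005, 0.02, [("chr4", "terminal")]),
    ]
    plans = []
    for name, unit, at, abundance_pct, age, loci in spec:
        n_units = max(5 * len(loci), int(round(abundance_pct / 100 * genome_bp / unit)))
        extra = {}
        if name == "SynFam05":
            extra["subrepeat_period"] = 155
        if name == "SynFam02":
            extra.update(ancestor="SynFam01", ancestor_divergence=0.30)
        if name == "SynFam04":
            extra["te_fragment"] = ("synTE_Copia-1", 0.5)
        plans.append(
            FamilyPlan(
                name=name, unit_length=unit, at_target=at, n_units_clustered=n_units,
                array_loci=loci, mutation_age=age, **extra,
            )
        )
    return plans


def default_distribution_plans() -> tuple[list[ChromosomeSpec], list[FamilyPlan]]:
    """Four chromosomes and one family per chromosomal distribution class.

    Used to exercise the assembly-mapping classifier: a strictly terminal
    family, a strictly (peri)centromeric one, one with mixed major loci
    (Multiple locations) and one present only as scattered 1-3 unit tandems
    (Dispersed).
    """
    chroms = [
        ChromosomeSpec(f"chr{i + 1}", 500_000, int(0.45 * 500_000), telomere_repeats=30)
        for i in range(4)
    ]
    plans = [
        FamilyPlan("TermFam", 300, at_target=0.55, n_units_clustered=30,
                   array_loci=[("chr1", "terminal"), ("chr2", "terminal")],
                   mutation_age=0.03),
        FamilyPlan("CenFam", 400, at_target=0.45, n_units_clustered=30,
                   array_loci=[("chr1", "pericentromeric"), ("chr3", "pericentromeric")],
                   mutation_age=0.03),
        FamilyPlan("MultiFam", 250, at_target=0.60, n_units_clustered=30,
                   array_loci=[("chr2", "terminal"), ("chr4", "interstitial")],
                   mutation_age=0.03),
        FamilyPlan("DispFam", 180, at_target=0.50, n_units_clustered=0,
                   n_dispersed_units=120, mutation_age=0.03),
    ]
    return chroms, plans


def load_te_library() -> dict[str, str]:
    """The small synthetic TE consensus library shipped for tests and demos."""
    from importlib.resources import files

    text = files("satkit.data").joinpath("te_library_synthetic.fa").read_text()
    lib: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            lib[name] = ""
        elif name:
            lib[name] += line.strip().upper()
    return lib
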