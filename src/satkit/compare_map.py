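"""Inter-family comparison and assembly-level mapping of satDNA families.

Monomer-vs-monomer similarity is rotation- and strand-aware (satDNA units
have arbitrary phase), superfamilies are single-linkage groups of homologous
families, TE homology is a local-alignment screen against a user-supplied TE
consensus library, and assembly mapping is a seed-and-extend search whose
hits are merged into tandem arrays and classified into the FISH-style
distribution classes (Terminal, (peri)centromeric, Multiple locations,
Dispersed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np

from ._alignment import kmer_codes, local_identity, revcomp
from .synthetic import TELOMERE_MOTIF, ChromosomeSpec


@dataclass
class PairSimilarity:
    family_a: str
    family_b: str
    identity: float           # percent, best over rotations x strands
    aligned_fraction: float   # of the shorter monomer
    offset: int               # rotation offset of b at the best alignment
    strand: str
    score: float = 0.0        # local alignment score of the best block


@dataclass
class AssemblyHit:
    chromosome: str
    start: int
    end: int
    strand: str
    identity: float  # percent


@dataclass
class TandemArray:
    chromosome: str
    start: int
    end: int
    n_units: int
    mean_identity: float
    strand: str


@dataclass
class DistributionCall:
    family: str
    label: str
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Rotational similarity & superfamilies
# ---------------------------------------------------------------------------

def rotational_alignment(a: str, b: str, name_a: str = "A", name_b: str = "B") -> PairSimilarity:
    """Best local alignment of monomer *a* against all rotations/strands of *b*.

    *b* is doubled so every rotation is a substring; identity is percent
    identical columns over the best local block, and aligned_fraction is the
    block's extent on the shorter monomer.
    """
    if len(a) < 20 or len(b) < 20:
        raise ValueError("monomers must be >= 20 bp")
    doubled = b + b
    best = None
    for strand, target in (("+", doubled), ("-", revcomp(doubled))):
        ident, cols, a_span, b_span, score = local_identity(a, target)
        if best is None or ident * cols > best[0] * best[1]:
            short = min(len(a), len(b))
            extent = min(a_span[1] - a_span[0], short) if len(a) <= len(b) else \
                min(b_span[1] - b_span[0], len(b))
            offset = b_span[0] % len(b)
            if strand == "-":
                offset = (len(doubled) - b_span[1]) % len(b)
            best = (ident, cols, extent / short, offset, strand, score)
    ident, _, fraction, offset, strand, score = best
    return PairSimilarity(name_a, name_b, 100.0 * ident, fraction, offset, strand, score)


def group_superfamilies(monomers: dict[str, str], min_identity: float = 65.0,
                        min_aligned_fraction: float = 0.25,
                        min_score: float = 30.0) -> dict[str, str | None]:
    """Single-linkage superfamily labels; singletons get None.

    Two families are linked when their best rotational alignment reaches
    ``min_identity`` percent over at least ``min_aligned_fraction`` of the
    shorter monomer with a local score of at least ``min_score`` (the score
    floor keeps chance low-identity blocks between short unrelated monomers
    from forging links; the empirical random-sequence null stays below ~25);
    connected components of two or more families become SF-1, SF-2, ...
    (numbered by first appearance in the input order).
    """
    names = list(monomers)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sim = rotational_alignment(monomers[a], monomers[b], a, b)
            if (sim.identity >= min_identity and sim.aligned_fraction >= min_aligned_fraction
                    and sim.score >= min_score):
                graph.add_edge(a, b)
    labels: dict[str, str | None] = {n: None for n in names}
    components = sorted(
        (c for c in nx.connected_components(graph) if len(c) >= 2),
        key=lambda c: min(names.index(n) for n in c),
    )
    for k, comp in enumerate(components, start=1):
        for n in comp:
            labels[n] = f"SF-{k}"
    return labels


def te_homology(monomer: str, te_library: dict[str, tuple[str, str]],
                min_identity: float = 60.0, min_coverage: float = 5.0,
                min_score: float = 30.0) -> list[dict]:
    """Local-alignment screen of a monomer against a TE consensus library.

    ``te_library`` maps TE name -> (sequence, class). Coverage is the percent
    of the monomer covered by the best local block against that TE; hits
    below the identity or coverage floors are suppressed, as are blocks whose
    local alignment score (+1/-1/affine gaps) falls below ``min_score`` -
    long low-identity blocks arise by chance between unrelated sequences
    (the empirical null tops out around score ~23), so the score floor plays
    the role of the complexity-adjusted score cutoff of classic repeat
    screens.
    """
    import warnings

    from ._alignment import _local_aligner

    if not te_library:
        warnings.warn("empty TE library; no homology search performed", stacklevel=2)
        return []
    aligner = _local_aligner()
    hits = []
    for te_name, (te_seq, te_class) in te_library.items():
        best = None
        for strand, target in (("+", te_seq), ("-", revcomp(te_seq))):
            score = aligner.score(monomer, target)
            if best is None or score > best[0]:
                best = (score, strand, target)
        score, strand, target = best
        if score < min_score:
            continue
        ident, cols, a_span, _, _ = local_identity(monomer, target)
        cov = 100.0 * (a_span[1] - a_span[0]) / len(monomer)
        if 100.0 * ident >= min_identity and cov >= min_coverage:
            hits.append({"te_name": te_name, "te_class": te_class, "score": float(score),
                         "coverage": cov, "identity": 100.0 * ident, "strand": strand})
    hits.sort(key=lambda h: -h["coverage"])
    return hits


def load_te_library_fasta(path) -> dict[str, tuple[str, str]]:
    """Read a TE library FASTA whose headers carry ``class=...`` tags."""
    lib: dict[str, tuple[str, str]] = {}
    name, cls, chunks = None, "Unknown", []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            if line.startswith(">"):
                if name:
                    lib[name] = ("".join(chunks).upper(), cls)
                parts = line[1:].split()
                name = parts[0]
                cls = next((p.split("=", 1)[1] for p in parts[1:] if p.startswith("class=")),
                           "Unknown")
                chunks = []
            else:
                chunks.append(line)
    if name:
        lib[name] = ("".join(chunks).upper(), cls)
    return lib


# ---------------------------------------------------------------------------
# Assembly search
# ---------------------------------------------------------------------------

def _seed_positions(query: str, target_codes: np.ndarray, k: int) -> np.ndarray:
    """Target positions where any exact k-mer of *query* occurs (non-canonical)."""
    qk = set(kmer_codes(query, k, canonical=False).tolist())
    n = len(target_codes) - k + 1
    if n <= 0 or not qk:
        return np.empty(0, dtype=np.int64)
    valid = target_codes < 4
    window_ok = np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target_codes.astype(np.int64), k)
    codes = windows @ weights
    hitmask = np.isin(codes, np.fromiter(qk, dtype=np.int64)) & window_ok
    return np.flatnonzero(hitmask)


def search_assembly(monomer: str, assembly: dict[str, str], seed_k: int = 13,
                    min_identity: float = 70.0, min_len_frac: float = 0.5) -> list[AssemblyHit]:
    """Seed-and-extend search of a monomer against assembly sequences.

    Exact ``seed_k``-mers anchor candidate regions; each region is tiled by
    repeated end-gap-free alignments of the monomer (edlib), so a tandem
    array decomposes into unit-scale hits. Hits need identity >=
    ``min_identity`` percent over >= ``min_len_frac`` x unit length; minus
    strand hits are reported on forward coordinates.
    """
    from ._alignment import encode

    L = len(monomer)
    hits: list[AssemblyHit] = []
    for chrom, seq in assembly.items():
        codes = encode(seq)
        for strand, query in (("+", monomer), ("-", revcomp(monomer))):
            pos = _seed_positions(query, codes, seed_k)
            if len(pos) == 0:
                continue
            # candidate regions: seed positions merged within one unit length
            gaps = np.flatnonzero(np.diff(pos) > L)
            starts = np.concatenate(([0], gaps + 1))
            ends = np.concatenate((gaps, [len(pos) - 1]))
            for s, e in zip(starts, ends):
                lo = max(0, int(pos[s]) - L)
                hi = min(len(seq), int(pos[e]) + seed_k + L)
                hits.extend(
                    _tile_region(query, seq, chrom, strand, lo, hi, min_identity, min_len_frac)
                )
    hits.sort(key=lambda h: (h.chromosome, h.start, h.end))
    return _dedup_hits(hits)


def _tile_region(query: str, seq: str, chrom: str, strand: str, lo: int, hi: int,
                 min_identity: float, min_len_frac: float) -> list[AssemblyHit]:
    """Recursively peel best end-gap-free placements of *query* out of seq[lo:hi]."""
    out: list[AssemblyHit] = []
    stack = [(lo, hi)]
    max_dist = int(len(query) * (1 - min_identity / 100.0))
    while stack:
        a, b = stack.pop()
        if b - a < int(min_len_frac * len(query)):
            continue
        segment = seq[a:b]
        res = edlib.align(query, segment, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        s, e = res["locations"][0]
        e += 1
        identity = 100.0 * (1 - res["editDistance"] / len(query))
        if e - s >= int(min_len_frac * len(query)) and identity >= min_identity:
            out.append(AssemblyHit(chrom, a + s, a + e, strand, identity))
        # recurse on both flanks
        if s > 0:
            stack.append((a, a + s))
        if a + e < b:
            stack.append((a + e, b))
    return out


def _dedup_hits(hits: list[AssemblyHit]) -> list[AssemblyHit]:
    """Drop hits overlapping a better hit by more than half of either span."""
    kept: list[AssemblyHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity, h.start)):
        clash = False
        for k in kept:
            if k.chromosome != h.chromosome:
                continue
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0.5 * min(h.end - h.start, k.end - k.start):
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.chromosome, h.start))
    return kept


def merge_hits_to_arrays(hits: list[AssemblyHit], unit_length: int,
                         max_gap: int | None = None) -> list[TandemArray]:
    """Merge same-strand hits with inter-hit gaps <= max_gap into tandem arrays.

    ``max_gap`` defaults to 0.2 x unit length. n_units = round(array length /
    unit length), floored at 1. Idempotent: merging the merged arrays again
    changes nothing.
    """
    if max_gap is None:
        max_gap = int(0.2 * unit_length)
    arrays: list[TandemArray] = []
    ordered = sorted(hits, key=lambda h: (h.chromosome, h.strand, h.start))
    current: list[AssemblyHit] = []

    def _flush():
        if not current:
            return
        start, end = current[0].start, max(h.end for h in current)
        arrays.append(
            TandemArray(
                current[0].chromosome, start, end,
                max(1, int(round((end - start) / unit_length))),
                float(np.mean([h.identity for h in current])),
                current[0].strand,
            )
        )
        current.clear()

    for h in ordered:
        if current and (
            h.chromosome != current[-1].chromosome
            or h.strand != current[-1].strand
            or h.start - max(x.end for x in current) > max_gap
        ):
            _flush()
        current.append(h)
    _flush()
    arrays.sort(key=lambda a: (a.chromosome, a.start))
    return arrays


# ---------------------------------------------------------------------------
# Terminal windows, telomeres, distribution classes
# ---------------------------------------------------------------------------

def terminal_window_size(chrom_length: int, window: int = 500_000) -> int:
    """Distal window used for 'terminal' calls: the stated window capped at 5%
    of the chromosome (desk-scale chromosomes are far below 500 kb x 2)."""
    return min(window, max(1, int(0.05 * chrom_length)))


def scan_terminal_windows(assembly: dict[str, str], window: int,
                          hits_by_family: dict[str, list[AssemblyHit]]) -> dict:
    """Telomere-motif presence and per-family copy counts in terminal windows.

    A chromosome end is telomere-positive iff >= 3 consecutive TTTAGGG units
    (strand-appropriate) occur within the terminal 1 kb. Raises when a window
    does not fit a chromosome.
    """
    for chrom, seq in assembly.items():
        if len(seq) < 2 * window:
            raise ValueError(f"window {window} does not fit chromosome {chrom}")
    out = {}
    probe_left = TELOMERE_MOTIF * 3
    probe_right = revcomp(TELOMERE_MOTIF) * 3
    for chrom, seq in assembly.items():
        ends = {
            "left": {"telomere": probe_left in seq[:1000], "families": {}},
            "right": {"telomere": probe_right in seq[-1000:], "families": {}},
        }
        for fam, hits in hits_by_family.items():
            left = sum(1 for h in hits if h.chromosome == chrom and h.start < window)
            right = sum(1 for h in hits if h.chromosome == chrom and h.end > len(seq) - window)
            ends["left"]["families"][fam] = left
            ends["right"]["families"][fam] = right
        out[chrom] = ends
    return out


def classify_distribution(family: str, arrays: list[TandemArray],
                          chromosomes: list[ChromosomeSpec],
                          major_locus_units: int = 5, dispersed_min: int = 50,
                          pericentromere_fraction: float = 0.05,
                          terminal_window: int = 500_000) -> DistributionCall:
    """FISH-style distribution class of one family from its tandem arrays.

    A major locus (the in-silico analogue of a FISH-visible band) is an array
    of >= ``major_locus_units`` units. The family is Terminal when all major
    loci fall in distal windows, (peri)centromeric when all fall within
    +/-``pericentromere_fraction`` of chromosome length around the
    centromere, Dispersed when there is no major locus but >=
    ``dispersed_min`` minor loci spread over at least half the chromosomes,
    'absent' with no hits at all, and Multiple locations otherwise.
    """
    by_name = {c.name: c for c in chromosomes}
    if not arrays:
        return DistributionCall(family, "absent")
    major = [a for a in arrays if a.n_units >= major_locus_units]
    minor = [a for a in arrays if a.n_units < major_locus_units]
    positions = {"Terminal": 0, "(peri)centromeric": 0, "Interstitial": 0}
    for a in major:
        chrom = by_name[a.chromosome]
        w = terminal_window_size(chrom.length, terminal_window)
        cen_half = int(pericentromere_fraction * chrom.length)
        mid = (a.start + a.end) // 2
        if a.start < w or a.end > chrom.length - w:
            positions["Terminal"] += 1
        elif abs(mid - chrom.centromere_position) <= cen_half:
            positions["(peri)centromeric"] += 1
        else:
            positions["Interstitial"] += 1
    evidence = {"major": positions, "n_minor": len(minor),
                "chromosomes": len({a.chromosome for a in arrays})}
    if major:
        if positions["Terminal"] == len(major):
            return DistributionCall(family, "Terminal", evidence)
        if positions["(peri)centromeric"] == len(major):
            return DistributionCall(family, "(peri)centromeric", evidence)
        return DistributionCall(family, "Multiple locations", evidence)
    if len(minor) >= dispersed_min and evidence["chromosomes"] >= max(1, len(chromosomes) // 2):
        return DistributionCall(family, "Dispersed", evidence)
    return DistributionCall(family, "Multiple locations", evidence)


def write_hits_bed(hits: list[AssemblyHit], family: str, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chromosome}\t{h.start}\t{h.end}\t{family}\t"
                     f"{h.identity:.1f}\t{h.strand}\n")


def write_arrays_bed(arrays: list[TandemArray], family: str, path) -> None:
    with open(path, "w") as fh:
        for a in arrays:
            fh.write(f"{a.chromosome}\t{a.start}\t{a.end}\t{family}\t{a.n_units}\t{a.strand}\n")
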