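"""Repeat landscapes: abundance-by-divergence histograms per satDNA family.

Reads are aligned to each family's consensus monomer (doubled, both strands,
so tandem junctions and rotations are absorbed), the Kimura 2-parameter
distance of each aligned segment is computed from its transition (P) and
transversion (Q) fractions, and aligned nucleotides accrue to 1%-wide
divergence bins expressed as genome proportion. Three summary indices follow
the repeat-landscape literature:

* DIVPEAK - the divergence bin holding the most abundance; a degeneration
  index proportional to the time since the last amplification event.
* PEAK-SIZE - summed abundance within +/- 2% divergence of DIVPEAK.
* RPS (relative peak size) - PEAK-SIZE / total abundance (in percent); a
  homogenization index that is high right after an amplification burst.

Indel columns are excluded from both the substitution counts and the aligned
base count: K2P is a substitution model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._alignment import infix_alignment, revcomp

N_BINS = 71  # 1% bins spanning 0-70% divergence
MIN_ALIGN = 50
MIN_SEGMENT_IDENTITY = 0.65


class SaturatedDivergenceError(ValueError):
    """K2P is undefined: substitution fractions beyond the model's domain."""


@dataclass
class AlignedSegment:
    """One read-to-monomer alignment reduced to what the landscape needs."""

    read_id: str
    monomer_id: str
    aligned_length: int     # matched columns only (indels excluded)
    transitions: int
    transversions: int

    @property
    def divergence(self) -> float:
        return kimura2p(self.transitions / self.aligned_length,
                        self.transversions / self.aligned_length)


@dataclass
class RepeatLandscape:
    monomer_id: str
    abundance: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS))
    total_abundance: float = 0.0

    @property
    def divpeak(self) -> int | None:
        return divpeak(self)

    @property
    def peak_size(self) -> float | None:
        ps_rps = peak_size_and_rps(self)
        return None if ps_rps is None else ps_rps[0]

    @property
    def rps(self) -> float | None:
        ps_rps = peak_size_and_rps(self)
        return None if ps_rps is None else ps_rps[1]

    def mean_divergence(self) -> float | None:
        """Abundance-weighted mean divergence (fraction), bin midpoints."""
        if self.total_abundance <= 0:
            return None
        mids = (np.arange(N_BINS) + 0.5) / 100.0
        return float((self.abundance * mids).sum() / self.total_abundance)


def kimura2p(p: float, q: float) -> float:
    """Kimura 2-parameter distance K = -1/2 ln((1-2p-q) sqrt(1-2q)).

    *p* is the transition fraction and *q* the transversion fraction of
    compared sites; the result is expected substitutions per site.
    """
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        raise SaturatedDivergenceError(f"saturated substitution fractions p={p}, q={q}")
    return -0.5 * math.log(a * math.sqrt(b))


def genome_proportion(aligned_bp: int, total_bp: int) -> float:
    """Fraction of sequenced nucleotides aligned to a family's monomer."""
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    if aligned_bp > total_bp:
        raise ValueError("aligned_bp cannot exceed total_bp")
    return aligned_bp / total_bp


def align_to_monomer(read: str, monomer: str, monomer_id: str = "", read_id: str = "",
                     min_align: int = MIN_ALIGN,
                     min_identity: float = MIN_SEGMENT_IDENTITY) -> AlignedSegment | None:
    """Best alignment of *read* against the doubled monomer, either strand.

    Returns None when no segment reaches ``min_identity`` over
    ``min_align`` matched columns.
    """
    if len(monomer) < 10:
        raise ValueError("monomer must be >= 10 bp")
    doubled = monomer + monomer
    best = None
    for target in (doubled, revcomp(doubled)):
        res = infix_alignment(read, target)
        if res is None:
            continue
        matches, mismatches, ts, tv, matched_cols, total_cols, _ = res
        if matched_cols == 0 or total_cols == 0:
            continue
        identity = matches / total_cols
        if best is None or identity > best[0]:
            best = (identity, matched_cols, ts, tv)
    if best is None:
        return None
    identity, matched_cols, ts, tv = best
    if identity < min_identity or matched_cols < min_align:
        return None
    return AlignedSegment(read_id, monomer_id, matched_cols, ts, tv)


def build_landscape(segments: list[AlignedSegment], total_bp: int,
                    monomer_id: str | None = None) -> RepeatLandscape:
    """Accrue each segment's aligned bp to the bin floor(K x 100).

    Segments whose substitution fractions saturate the K2P domain are skipped
    (they would not have passed the identity threshold of the aligner in any
    realistic run). Conservation: the bins sum exactly to total_abundance.
    """
    ids = {s.monomer_id for s in segments if s.monomer_id}
    if monomer_id is None:
        monomer_id = ids.pop() if len(ids) == 1 else ""
    elif len(ids) > 1 or (ids and ids != {monomer_id}):
        raise ValueError("segments for multiple monomers passed to one landscape")
    ls = RepeatLandscape(monomer_id)
    for seg in segments:
        try:
            k = seg.divergence
        except SaturatedDivergenceError:
            continue
        b = min(N_BINS - 1, int(k * 100))
        ls.abundance[b] += seg.aligned_length / total_bp
    ls.total_abundance = float(ls.abundance.sum())
    return ls


def divpeak(landscape: RepeatLandscape) -> int | None:
    """Argmax divergence bin; ties break toward lower divergence; None if empty."""
    if landscape.total_abundance <= 0:
        return None
    return int(np.argmax(landscape.abundance))


def peak_size_and_rps(landscape: RepeatLandscape) -> tuple[float, float] | None:
    """(PEAK-SIZE, RPS%) around DIVPEAK; None for an empty landscape."""
    dp = divpeak(landscape)
    if dp is None:
        return None
    lo, hi = max(0, dp - 2), min(N_BINS - 1, dp + 2)
    peak = float(landscape.abundance[lo:hi + 1].sum())
    return peak, 100.0 * peak / landscape.total_abundance


def _probe_kmers(seq: str, k: int = 11, step: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1, step)}


def compute_landscapes(monomers: dict[str, str], pairs: list, sample_pairs: int | None = None,
                       seed: int = 0, min_align: int = MIN_ALIGN,
                       min_identity: float = MIN_SEGMENT_IDENTITY):
    """Landscapes for a monomer database from a read sample.

    Each read is assigned to the single best-matching monomer (as a
    RepeatMasker-style screen would) so related families do not double-count
    the same nucleotides. Returns ``(landscapes, total_bp)`` where
    ``landscapes`` maps monomer id -> RepeatLandscape.
    """
    from .mining import sample_reads

    if sample_pairs is not None and sample_pairs < len(pairs):
        pairs = sample_reads(pairs, sample_pairs, seed)
    reads = [(f"{p.name}/{i + 1}", s) for p in pairs for i, s in enumerate((p.seq1, p.seq2))]
    total_bp = sum(len(s) for _, s in reads)
    targets = {}
    target_kmers = {}
    for mid, seq in monomers.items():
        doubled = seq + seq
        targets[mid] = doubled
        target_kmers[mid] = _probe_kmers(doubled) | _probe_kmers(revcomp(doubled))
    segments: dict[str, list[AlignedSegment]] = {mid: [] for mid in monomers}
    for rid, seq in reads:
        probe = _probe_kmers(seq, step=1)
        best = None
        for mid in monomers:
            if not (probe & target_kmers[mid]):
                continue
            seg = align_to_monomer(seq, monomers[mid], mid, rid, min_align, min_identity)
            if seg is None:
                continue
            ident = 1.0 - (seg.transitions + seg.transversions) / seg.aligned_length
            key = (seg.aligned_length * ident, ident)
            if best is None or key > best[0]:
                best = (key, seg)
        if best is not None:
            segments[best[1].monomer_id].append(best[1])
    landscapes = {
        mid: build_landscape(segs, total_bp, mid) for mid, segs in segments.items()
    }
    return landscapes, total_bp


def landscape_table(landscapes: dict[str, RepeatLandscape]):
    """Long-format DataFrame (family, bin, abundance) for saving or plotting."""
    import pandas as pd

    rows = []
    for mid, ls in landscapes.items():
        for b in range(N_BINS):
            rows.append({"family": mid, "divergence_bin": b, "abundance": ls.abundance[b]})
    return pd.DataFrame(rows)


def plot_landscape(landscape: RepeatLandscape, path=None):
    """Barplot of one repeat landscape; returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(np.arange(N_BINS), 100 * landscape.abundance, width=1.0, color="#46739c")
    ax.set_xlabel("K2P divergence (%)")
    ax.set_ylabel("genome proportion (%)")
    ax.set_title(landscape.monomer_id)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax
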