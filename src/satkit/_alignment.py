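"""Shared low-level sequence and alignment helpers.

Conventions used throughout the package:

* sequences are plain upper-case ``str`` over the alphabet ``ACGTN``;
* genomic coordinates are 0-based half-open;
* a satDNA monomer is treated as circular, so alignments against a monomer
  are performed against the doubled sequence to absorb tandem junctions and
  arbitrary rotations.
"""

from __future__ import annotations

from functools import lru_cache

import edlib
import numpy as np
from Bio import Align

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: 2-bit base codes used by the k-mer machinery (N maps to 4 and is dropped).
BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    BASE_CODE[ord(_b)] = _i
    BASE_CODE[ord(_b.lower())] = _i

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N-safe)."""
    return seq.translate(_COMP)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True if the substitution a->b is a transition (purine<->purine or pyrimidine<->pyrimidine)."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """All k-mer integer codes of *seq* (k-mers containing N are dropped).

    With ``canonical=True`` each k-mer is replaced by the smaller of itself
    and its reverse complement so the result is strand-agnostic.
    """
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    window_ok = np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    fwd = windows @ weights
    if not canonical:
        return fwd[window_ok]
    rc_codes = (3 - codes[::-1]) % 4  # N handled by window_ok mask
    rc_windows = np.lib.stride_tricks.sliding_window_view(rc_codes.astype(np.int64), k)
    rev = (rc_windows @ weights)[::-1]
    return np.minimum(fwd, rev)[window_ok]


def least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation of *s* (two-pointer scan)."""
    ss = s + s
    n = len(s)
    i, j, k = 0, 1, 0
    while i < n and j < n and k < n:
        a, b = ss[i + k], ss[j + k]
        if a == b:
            k += 1
            continue
        if a > b:
            i = max(i + k + 1, j)
            if i == j:
                i += 1
        else:
            j = max(j + k + 1, i)
            if i == j:
                j += 1
        k = 0
    return min(i, j)


def canonical_rotation(seq: str) -> str:
    """Canonical form of a circular monomer.

    The lexicographically minimal rotation over both strands; this gives every
    satDNA family one stable representative sequence independent of the phase
    and strand in which it was assembled.
    """
    seq = seq.upper()
    rc = revcomp(seq)
    a = seq[least_rotation(seq):] + seq[:least_rotation(seq)]
    b = rc[least_rotation(rc):] + rc[:least_rotation(rc)]
    return min(a, b)


def rotate(seq: str, offset: int) -> str:
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


@lru_cache(maxsize=4)
def _local_aligner(match: float = 1.0, mismatch: float = -1.0,
                   gap_open: float = -2.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_identity(a: str, b: str):
    """Best local alignment of *a* vs *b*.

    Returns ``(identity, columns, a_span, b_span, score)`` where identity is
    the fraction of identical columns over all columns (gap columns included)
    of the best-scoring local block, spans are (start, end) in each sequence
    and score is the alignment score (+1 match / -1 mismatch / affine gaps).
    Returns ``(0.0, 0, (0, 0), (0, 0), 0.0)`` when no positive-scoring block
    exists.
    """
    aligner = _local_aligner()
    try:
        aln = next(iter(aligner.align(a, b)))
    except (StopIteration, OverflowError):
        return 0.0, 0, (0, 0), (0, 0), 0.0
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, 0, (0, 0), (0, 0), 0.0
    a_span = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
    b_span = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
    return counts.identities / columns, columns, a_span, b_span, float(aln.score)


def infix_identity(query: str, target: str) -> float:
    """Identity of the best infix alignment of the whole *query* inside *target*.

    Computed as ``1 - edit_distance / len(query)`` with end-gap-free placement
    in the target (edlib ``HW`` mode); clipped at 0.
    """
    if not query or not target:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(query))


@lru_cache(maxsize=1)
def _affine_aligner() -> Align.PairwiseAligner:
    # gaps cost clearly more than mismatches so that substitutions are not
    # rewritten as spurious indel pairs (unit-cost edit distance does exactly
    # that, deflating substitution counts on diverged sequences)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def infix_alignment(query: str, target: str):
    """Best infix alignment of *query* in *target* with per-column detail.

    The segment is located with edlib (``HW`` mode, fast) and then recounted
    from an affine-gap realignment of the located window, which keeps
    substitutions as substitutions. Returns ``(matches, mismatches,
    transitions, transversions, matched_cols, total_cols, target_span)`` or
    ``None`` when no alignment exists. Indel columns are excluded from
    ``matched_cols`` (substitution-model convention).
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    window = target[start:end + 1]
    try:
        aln = next(iter(_affine_aligner().align(window, query)))
    except (StopIteration, OverflowError):
        return None
    t_aln, q_aln = aln[0], aln[1]
    matches = mismatches = transitions = transversions = 0
    for qa, ta in zip(q_aln, t_aln):
        if qa == "-" or ta == "-":
            continue
        if qa == ta:
            matches += 1
        else:
            mismatches += 1
            if is_transition(qa, ta):
                transitions += 1
            else:
                transversions += 1
    matched_cols = matches + mismatches
    return matches, mismatches, transitions, transversions, matched_cols, len(q_aln), (start, end + 1)
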