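"""Structural characterization of satDNA consensus monomers.

Covers the classic descriptive battery for a satellite repeat unit: base
composition, internal direct subrepeats (the footprint of past unit-length
amplifications), inverted repeats / dyad symmetries (substrate for hairpin
and cruciform non-B DNA), a nearest-neighbor hairpin free-energy estimate,
and a sliding-window curvature-propensity profile.

The monomer is treated as circular throughout: satDNA units are tandem, so
the phase of the consensus is arbitrary and window scans wrap around.

The hairpin dG is an explicit simplification of full minimum-free-energy
folding: only single perfect-stem hairpins are enumerated (no multiloops,
bulges or dangles), scored with unified nearest-neighbor parameters at 37
degC plus a tabulated hairpin-loop penalty. It is a comparative stability
index, not a full secondary-structure prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._alignment import encode, revcomp

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class DirectSubrepeat:
    period: int
    copies: int
    start: int
    identity: float
    fraction_of_monomer: float


@dataclass
class InvertedRepeat:
    stem: int
    loop: int
    left_start: int     # first base of the left arm
    right_start: int    # first base of the right arm
    mismatches: int

    @property
    def span(self) -> tuple[int, int]:
        return self.left_start, self.right_start + self.stem


@dataclass
class CurvatureProfile:
    values: np.ndarray  # degrees per 10.5-bp helical turn, one per position
    window: int

    @property
    def peak_value(self) -> float:
        return float(np.nanmax(self.values))

    @property
    def peak_position(self) -> int:
        return int(np.nanargmax(self.values))


@dataclass
class HairpinStructure:
    left_start: int
    stem: int
    loop: int
    dg: float


@dataclass
class MonomerStructureReport:
    name: str
    at_percent: float | None
    subrepeats: list[DirectSubrepeat]
    inverted_repeats: list[InvertedRepeat]
    hairpin_dg: float
    hairpin: HairpinStructure | None
    curvature: CurvatureProfile
    curvature_class: str


def at_content(seq: str) -> float | None:
    """A+T percentage over unambiguous bases; None if the sequence is all N."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        return None
    return 100.0 * at / acgt


# ---------------------------------------------------------------------------
# Direct subrepeats
# ---------------------------------------------------------------------------

def tandem_identity(seq: str, period: int) -> tuple[float, int]:
    """Column-consensus identity of the circular tiling of *seq* at *period*.

    The monomer is wrapped into floor(L/period) rows of ``period`` columns
    (circular indexing); identity is the fraction of cells agreeing with
    their column consensus. Returns ``(identity, copies)``.
    """
    L = len(seq)
    copies = L // period
    codes = encode(seq)
    idx = (np.arange(copies)[:, None] * period + np.arange(period)[None, :]) % L
    cells = codes[idx]
    onehot = np.zeros((period, 5), dtype=np.int32)
    for b in range(5):
        onehot[:, b] = (cells == b).sum(axis=0)
    col_max = onehot[:, :4].max(axis=1)
    return float(col_max.sum() / (period * copies)), copies


def find_direct_subrepeats(seq: str, min_period: int = 3, min_identity: float = 0.6,
                           min_copies: int = 2) -> list[DirectSubrepeat]:
    """Internal tandem subrepeats of the (circular) monomer.

    Every period in [min_period, L/2] is scored by circular column-consensus
    identity; qualifying periods that are near-multiples of a smaller
    qualifying period with comparable identity are suppressed, so a unit
    built as 4 x 155 bp reports period 155, not 310. Results are sorted by
    explained fraction x identity, best first.
    """
    L = len(seq)
    if L < 2 * min_period:
        return []
    hits: list[DirectSubrepeat] = []
    for p in range(min_period, L // 2 + 1):
        ident, copies = tandem_identity(seq, p)
        if copies >= min_copies and ident >= min_identity:
            hits.append(DirectSubrepeat(p, copies, 0, ident, p * copies / L))
    hits.sort(key=lambda h: h.period)
    kept: list[DirectSubrepeat] = []
    for h in hits:
        redundant = any(
            h.period % k.period == 0 and h.identity <= k.identity + 0.05 for k in kept
        )
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (-h.fraction_of_monomer * h.identity, h.period))
    return kept


# ---------------------------------------------------------------------------
# Inverted repeats / dyad symmetries
# ---------------------------------------------------------------------------

def find_inverted_repeats(seq: str, min_stem: int = 5, max_loop: int = 100,
                          max_mismatch: int = 0) -> list[InvertedRepeat]:
    """All maximal inverted repeats of the linear monomer.

    An inverted repeat is a left arm whose reverse complement reappears after
    a loop of at most ``max_loop`` bases; stems extend outward from every
    center until the mismatch budget is exceeded, and hits nested inside a
    longer hit (both arms contained, same or larger stem) are suppressed.
    """
    seq = seq.upper()
    L = len(seq)
    if L < 2 * min_stem:
        return []
    raw: list[InvertedRepeat] = []
    for loop in range(0, max_loop + 1):
        for i in range(L - loop - 1):
            # left arm ends at i (inclusive); right arm starts at i + loop + 1
            j = i + loop + 1
            t = mism = best_len = best_mm = 0
            while i - t >= 0 and j + t < L:
                match = _COMPLEMENT.get(seq[i - t]) == seq[j + t]
                if not match:
                    mism += 1
                    if mism > max_mismatch:
                        break
                t += 1
                if match:  # a maximal stem never ends on a mismatch
                    best_len, best_mm = t, mism
            if best_len >= min_stem:
                raw.append(InvertedRepeat(best_len, loop, i - best_len + 1, j, best_mm))
    # maximality: drop hits whose both arms nest inside a longer hit's arms
    raw.sort(key=lambda h: (-h.stem, h.loop, h.left_start))
    kept: list[InvertedRepeat] = []
    for h in raw:
        contained = any(
            k.left_start <= h.left_start
            and h.left_start + h.stem <= k.left_start + k.stem
            and k.right_start <= h.right_start
            and h.right_start + h.stem <= k.right_start + k.stem
            for k in kept
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.left_start, h.loop))
    return kept


# ---------------------------------------------------------------------------
# Hairpin free energy (nearest-neighbor, hairpin-only)
# ---------------------------------------------------------------------------

#: Unified nearest-neighbor dG37 (kcal/mol) for DNA stacks, 1 M NaCl.
NN_DG37 = {
    "AA": -1.00, "AT": -0.88, "TA": -0.58, "CA": -1.45, "GT": -1.44,
    "CT": -1.28, "GA": -1.30, "CG": -2.17, "GC": -2.24, "GG": -1.84,
}

#: Hairpin loop penalties dG37 (kcal/mol) by loop length.
HAIRPIN_LOOP_DG37 = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.6,
    12: 5.0, 14: 5.1, 16: 5.3, 18: 5.5, 20: 5.7, 25: 6.1, 30: 6.3,
}

_R = 0.0019872  # kcal/(mol K)
_T37 = 310.15


def _stack_dg(dinuc: str) -> float:
    if dinuc in NN_DG37:
        return NN_DG37[dinuc]
    return NN_DG37[revcomp(dinuc)]


def loop_penalty(n: int) -> float:
    """Hairpin loop dG37; tabulated, linearly interpolated, Jacobson-Stockmayer
    extrapolated beyond 30 nt."""
    if n < 3:
        raise ValueError("hairpin loops need >= 3 nt")
    sizes = sorted(HAIRPIN_LOOP_DG37)
    if n in HAIRPIN_LOOP_DG37:
        return HAIRPIN_LOOP_DG37[n]
    if n > sizes[-1]:
        return HAIRPIN_LOOP_DG37[sizes[-1]] + 1.75 * _R * _T37 * math.log(n / sizes[-1])
    lo = max(s for s in sizes if s < n)
    hi = min(s for s in sizes if s > n)
    frac = (n - lo) / (hi - lo)
    return HAIRPIN_LOOP_DG37[lo] + frac * (HAIRPIN_LOOP_DG37[hi] - HAIRPIN_LOOP_DG37[lo])


def stem_dg(stem_seq: str, loop: int) -> float:
    """dG of one perfect hairpin: NN stacks along the stem plus loop penalty.

    ``stem_seq`` is the left arm read 5'->3' toward the loop.
    """
    dg = loop_penalty(loop)
    for i in range(len(stem_seq) - 1):
        dg += _stack_dg(stem_seq[i:i + 2])
    return dg


def hairpin_dG(seq: str, temperature: float = 37.0,
               min_stem: int = 3, max_loop: int = 30) -> tuple[float, HairpinStructure | None]:
    """Most stable single hairpin of the monomer (lower bound on folding dG).

    Enumerates perfect-stem inverted repeats with loop 3..max_loop and scores
    each with the nearest-neighbor table; returns ``(dG, structure)`` or
    ``(0.0, None)`` when nothing folds. Only the 37 degC parameter set is
    embedded.
    """
    if len(seq) < 10:
        raise ValueError("monomer must be >= 10 bp")
    if abs(temperature - 37.0) > 1e-9:
        raise NotImplementedError("only the 37 degC parameter table is embedded")
    seq = seq.upper()
    best_dg, best = 0.0, None
    for ir in find_inverted_repeats(seq, min_stem=min_stem, max_loop=max_loop, max_mismatch=0):
        if ir.loop < 3:
            continue
        arm = seq[ir.left_start: ir.left_start + ir.stem]
        dg = stem_dg(arm, ir.loop)
        if dg < best_dg:
            best_dg = dg
            best = HairpinStructure(ir.left_start, ir.stem, ir.loop, dg)
    return best_dg, best


# ---------------------------------------------------------------------------
# Curvature propensity
# ---------------------------------------------------------------------------

#: DNase I based trinucleotide bendability values (Brukner-style 32-value
#: set, complementary trinucleotides share a value). Transcribed from the
#: secondary literature; treated as a relative scale.
BENDABILITY_DNASE = {
    "AAA": -0.274, "AAC": -0.205, "AAG": -0.081, "AAT": -0.280,
    "ACA": -0.006, "ACC": -0.032, "ACG": -0.033, "ACT": -0.183,
    "AGA": 0.027, "AGC": 0.017, "AGG": -0.057, "ATA": 0.182,
    "ATC": -0.110, "ATG": 0.134, "CAA": 0.015, "CAC": 0.040,
    "CAG": 0.175, "CCA": -0.246, "CCC": -0.012, "CCG": -0.136,
    "CGA": -0.003, "CGC": -0.077, "CTA": 0.090, "CTC": 0.031,
    "GAA": -0.037, "GAC": -0.013, "GCA": 0.076, "GCC": 0.107,
    "GGA": 0.013, "GTA": 0.025, "TAA": 0.068, "TCA": 0.194,
}

_B_VALUES = np.array(list(BENDABILITY_DNASE.values()))
_B_MIN, _B_MAX = float(_B_VALUES.min()), float(_B_VALUES.max())

#: Degrees per 10.5-bp helical turn corresponding to propensity 1.0. This is
#: a package-defined calibration of a synthetic curvature scale (see
#: curvature_propensity): rigid A-tract-like trinucleotides map near the
#: scale ceiling and flexible G/C-rich ones near the floor, so that phased
#: A-tracts score high and mixed-sequence DNA scores in the low range.
CURVATURE_DEGREES_SCALE = 10.0


def _trinuc_value(tri: str) -> float:
    if tri in BENDABILITY_DNASE:
        return BENDABILITY_DNASE[tri]
    rc = revcomp(tri)
    if rc in BENDABILITY_DNASE:
        return BENDABILITY_DNASE[rc]
    return math.nan  # contains N


def curvature_propensity(tri: str) -> float:
    """Synthetic curvature-propensity score of one trinucleotide in [0, 1].

    Defined as the min-max-inverted DNase I bendability (rigid => curved),
    a package-built stand-in for server-side curvature parameter sets that
    preserves the A-tract-high / G-tract-low ordering the method relies on.
    """
    b = _trinuc_value(tri)
    if math.isnan(b):
        return math.nan
    return (_B_MAX - b) / (_B_MAX - _B_MIN)


def curvature_profile(seq: str, window: int = 31) -> CurvatureProfile:
    """Smoothed per-position curvature propensity of the circular monomer.

    Each position takes the propensity of the trinucleotide starting there;
    a triangular window of ``window`` bp smooths the circular profile, and
    the result is scaled to degrees per 10.5-bp helical turn. Positions whose
    trinucleotide contains N are masked (NaN) before smoothing.
    """
    seq = seq.upper()
    L = len(seq)
    if L < window:
        raise ValueError("monomer shorter than the smoothing window")
    circ = seq + seq[:2]
    vals = np.array([curvature_propensity(circ[i:i + 3]) for i in range(L)])
    half = window // 2
    weights = np.concatenate([np.arange(1, half + 2), np.arange(half, 0, -1)]).astype(float)
    idx = (np.arange(L)[:, None] + np.arange(-half, half + 1)[None, :]) % L
    windowed = vals[idx]
    mask = np.isnan(windowed)
    w = np.where(mask, 0.0, weights[None, :])
    smoothed = np.where(mask, 0.0, np.nan_to_num(windowed)) * w
    denom = w.sum(axis=1)
    out = np.full(L, np.nan)
    ok = denom > 0
    out[ok] = smoothed[ok].sum(axis=1) / denom[ok]
    return CurvatureProfile(out * CURVATURE_DEGREES_SCALE, window)


def classify_curvature(profile: CurvatureProfile, threshold: float = 14.0) -> str:
    """'curved' iff the profile peak strictly exceeds the threshold."""
    return "curved" if profile.peak_value > threshold else "low"


def structure_report(name: str, seq: str, curvature_window: int = 31) -> MonomerStructureReport:
    """The full structural battery for one consensus monomer."""
    profile = curvature_profile(seq, curvature_window) if len(seq) >= curvature_window else \
        CurvatureProfile(np.zeros(len(seq)), len(seq))
    dg, hairpin = hairpin_dG(seq)
    return MonomerStructureReport(
        name=name,
        at_percent=at_content(seq),
        subrepeats=find_direct_subrepeats(seq),
        inverted_repeats=find_inverted_repeats(seq),
        hairpin_dg=dg,
        hairpin=hairpin,
        curvature=profile,
        curvature_class=classify_curvature(profile),
    )


def report_row(report: MonomerStructureReport) -> dict:
    """Flat dict (one TSV row) summarizing a structure report."""
    longest_ir = max((ir.stem for ir in report.inverted_repeats), default=0)
    n_ge10 = sum(1 for ir in report.inverted_repeats if ir.stem >= 10)
    best = report.subrepeats[0] if report.subrepeats else None
    return {
        "family": report.name,
        "at_percent": report.at_percent,
        "n_subrepeats": best.copies if best else 0,
        "subrepeat_period": best.period if best else 0,
        "longest_inverted": longest_ir,
        "n_inverted": len(report.inverted_repeats),
        "n_inverted_ge10": n_ge10,
        "hairpin_dg": report.hairpin_dg,
        "curvature_peak": report.curvature.peak_value,
        "curvature_class": report.curvature_class,
    }
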