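"""Iterative satDNA discovery from unassembled short reads.

Re-implements the satMiner-style loop: sample reads, build a read-similarity
graph, cluster it, detect clusters whose de Bruijn graph is dominated by a
cycle (the signature of a tandem repeat), reconstruct the monomer as the
maximum-mean-weight cycle, filter the library against everything found so
far, and repeat. Iterating lets rare families surface once abundant ones have
been subtracted from the library.

Clustering here is connected components over a thresholded overlap graph
(a deliberate desk-scale simplification of the reference tool's community
detection). Circularity is scored as read support for the best de Bruijn
cycle - a divergence-robust stand-in for the cluster-graph-topology index
used by TAREAN; the raw on-cycle weight fraction remains available as
:func:`cycle_weight_fraction`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np

from ._alignment import canonical_rotation, infix_identity, kmer_codes, revcomp

logger = logging.getLogger(__name__)


@dataclass
class MiningConfig:
    """Thresholds of the discovery loop; defaults follow the package run manifest."""

    k: int = 13                      # k-mer size of the overlap-graph candidate filter
    #  (21 would be natural but an exact 21-mer survives two ~10%-diverged
    #  unit copies with probability ~0.01, so aged families would never be
    #  proposed as candidate pairs; 13 keeps the filter selective while
    #  letting diverged units reach the alignment check)
    min_shared_kmers: int = 5        # canonical k-mers two reads must share
    min_identity: float = 0.8        # alignment identity for a graph edge
    min_cluster_size: int = 25       # reads per cluster worth analysing
    k_db: int = 21                   # de Bruijn k-mer size of the raw topology statistic
    k_db_ladder: tuple = (41, 31, 21, 13)  # word sizes tried for consensus extraction
    #  The ladder runs long-to-short: a long word keeps internally subrepeated
    #  monomers from short-circuiting onto their subunit cycle (two 10%-
    #  diverged subunit copies share an exact 21-mer often enough to create
    #  jump arcs, but almost never a 31-mer), while a short word keeps the
    #  consensus cycle of an aged family unbroken (an exact 21-mer survives a
    #  12%-diverged unit copy with probability ~0.07).
    min_cycle_coverage: float = 3.0  # aligned cluster bp per cycle bp; a real
    #  satellite tandems through its cluster several times, whereas a chance
    #  'lasso' cycle (a repeated word closing a unique genomic segment) is
    #  covered ~1x and is rejected by this gate
    min_junction_reads: int = 2      # reads whose alignment spans the monomer
    #  junction; tandem arrays produce them at every phase, a lasso produces
    #  none (its reads run linearly past the closing repeat)
    circ_threshold: float = 0.5      # minimum circularity for consensus building
    min_monomer: int = 20            # shortest reportable monomer (bp)
    filter_identity: float = 0.80    # read-vs-monomer identity for filtering
    filter_coverage: float = 0.50    # fraction of read that must match
    dedup_identity: float = 95.0     # rotational identity collapsing duplicate families
    max_kmer_occurrence: int = 2000  # k-mers seen in more reads are skipped for pairing
    min_edge_block: int = 31         # minimum local-alignment block (columns) for an edge
    max_edge_degree: int = 8         # stop confirming edges for a read past this degree
    circ_align_identity: float = 0.70  # read-to-cycle identity used by the circularity score
    max_dbg_nodes: int = 3000        # adaptive pruning target for the de Bruijn graph


@dataclass
class ReadCluster:
    """A connected component of the read-similarity graph."""

    read_ids: list[int]
    graph: nx.Graph
    genome_proportion: float
    circularity: float | None = None
    consensus_cycle: str | None = None
    junction_reads: int = 0


@dataclass
class ConsensusMonomer:
    name: str
    sequence: str
    unit_length: int
    n_reads: int
    round_index: int
    circularity: float
    genome_proportion: float = 0.0
    low_confidence: bool = False


def sample_reads(pairs: list, n_pairs: int, seed: int) -> list:
    """Uniform sample of read pairs without replacement (seed-deterministic)."""
    if n_pairs > len(pairs):
        raise ValueError(f"requested {n_pairs} pairs but library holds {len(pairs)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n_pairs, replace=False)
    return [pairs[i] for i in sorted(idx)]


def _edge_identity(a: str, b: str, cfg: MiningConfig) -> float | None:
    """Alignment identity used to confirm a candidate edge.

    Fast path: end-to-end edit identity (covers same-phase reads and reverse
    complements). Fallback: a local-alignment score screen that absorbs the
    phase shifts of reads drawn from different offsets of the same tandem
    array; accepted blocks report the identity implied by the score (exact
    identity is not recomputed for speed).
    """
    best = 0.0
    for bb in (b, revcomp(b)):
        res = edlib.align(a, bb, mode="NW", task="distance")
        ident = 1.0 - res["editDistance"] / max(len(a), len(bb))
        best = max(best, ident)
        if best >= cfg.min_identity:
            return best
    # with +1 match / -1 mismatch scoring a block of c columns at identity i
    # scores ~ c(2i - 1); require the score of a minimally long block
    min_score = cfg.min_edge_block * (2 * cfg.min_identity - 1)
    from ._alignment import _local_aligner

    aligner = _local_aligner()
    for bb in (b, revcomp(b)):
        score = aligner.score(a, bb)
        if score >= min_score:
            return min(1.0, (score / len(a) + 1) / 2)
    return None


def build_similarity_graph(reads: list[str], k: int = 13, min_shared_kmers: int = 5,
                           min_identity: float = 0.8,
                           cfg: MiningConfig | None = None) -> nx.Graph:
    """Strand-agnostic read-overlap graph.

    Edge (r1, r2) iff the reads share >= ``min_shared_kmers`` canonical
    k-mers and align at identity >= ``min_identity``.
    """
    cfg = cfg or MiningConfig(k=k, min_shared_kmers=min_shared_kmers, min_identity=min_identity)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(reads)))
    if not reads:
        return graph

    km_arrays, rid_arrays = [], []
    for rid, seq in enumerate(reads):
        km = np.unique(kmer_codes(seq, cfg.k))
        km_arrays.append(km)
        rid_arrays.append(np.full(len(km), rid, dtype=np.int64))
    kms = np.concatenate(km_arrays)
    rids = np.concatenate(rid_arrays)
    order = np.argsort(kms, kind="stable")
    kms, rids = kms[order], rids[order]
    # group boundaries of identical k-mers
    boundaries = np.flatnonzero(np.diff(kms)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(kms)]))

    pair_chunks = []
    triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for s, e in zip(starts, ends):
        size = e - s
        if size < 2 or size > cfg.max_kmer_occurrence:
            continue
        members = rids[s:e]
        if size not in triu_cache:
            triu_cache[size] = np.triu_indices(size, k=1)
        ii, jj = triu_cache[size]
        lo = np.minimum(members[ii], members[jj])
        hi = np.maximum(members[ii], members[jj])
        pair_chunks.append(lo * len(reads) + hi)
    if not pair_chunks:
        return graph
    keys, counts = np.unique(np.concatenate(pair_chunks), return_counts=True)
    ok = counts >= cfg.min_shared_kmers
    keys, counts = keys[ok], counts[ok]
    # confirm the strongest candidates first; a degree cap keeps dense
    # satellite cliques from costing quadratic alignment work (components,
    # not full cliques, are what clustering needs)
    order = np.argsort(-counts, kind="stable")
    degree = np.zeros(len(reads), dtype=np.int32)
    for key in keys[order]:
        r1, r2 = int(key // len(reads)), int(key % len(reads))
        if degree[r1] >= cfg.max_edge_degree and degree[r2] >= cfg.max_edge_degree:
            continue
        ident = _edge_identity(reads[r1], reads[r2], cfg)
        if ident is not None:
            graph.add_edge(r1, r2, identity=ident)
            degree[r1] += 1
            degree[r2] += 1
    return graph


def cluster_reads(graph: nx.Graph, reads: list[str], total_bp: int,
                  min_cluster_size: int = 25) -> list[ReadCluster]:
    """Connected components with >= min_cluster_size reads, largest first."""
    clusters = []
    for comp in nx.connected_components(graph):
        if len(comp) < min_cluster_size:
            continue
        ids = sorted(comp)
        bp = sum(len(reads[i]) for i in ids)
        clusters.append(ReadCluster(ids, graph.subgraph(ids).copy(), bp / total_bp))
    clusters.sort(key=lambda c: -len(c.read_ids))
    return clusters


# ---------------------------------------------------------------------------
# De Bruijn circularity and consensus
# ---------------------------------------------------------------------------

def build_debruijn(seqs: list[str], k: int = 21) -> dict[str, int]:
    """k-mer -> count over both strands of every sequence."""
    counts: dict[str, int] = {}
    for seq in seqs:
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                if "N" in km:
                    continue
                counts[km] = counts.get(km, 0) + 1
    return counts


def max_mean_weight_cycle(edges: list[tuple[int, int, float]], n_nodes: int):
    """Exact maximum-mean-weight cycle (Karp's algorithm, vectorized DP).

    Returns ``(mean_weight, cycle_nodes)`` where cycle_nodes is the vertex
    sequence (first == last omitted) of a cycle achieving the optimum, or
    ``(None, None)`` if the graph is acyclic.
    """
    if not edges or n_nodes == 0:
        return None, None
    eu = np.array([e[0] for e in edges], dtype=np.int64)
    ev = np.array([e[1] for e in edges], dtype=np.int64)
    ew = np.array([e[2] for e in edges], dtype=float)
    n = n_nodes
    NEG = -np.inf
    D = np.full((n + 1, n), NEG)
    P = np.full((n + 1, n), -1, dtype=np.int64)
    D[0] = 0.0
    for step in range(1, n + 1):
        cand = D[step - 1][eu] + ew
        Dk = np.full(n, NEG)
        np.maximum.at(Dk, ev, cand)
        D[step] = Dk
        achieved = np.flatnonzero((cand == Dk[ev]) & np.isfinite(cand))
        P[step][ev[achieved]] = achieved  # edge index realizing the optimum
    finite = np.isfinite(D[n])
    if not finite.any():
        return None, None
    with np.errstate(invalid="ignore"):
        ratios = (D[n][None, :] - D[:n]) / (n - np.arange(n))[:, None]
    ratios[:, ~finite] = np.inf
    ratios = np.where(np.isfinite(D[:n]), ratios, np.inf)
    per_vertex = ratios.min(axis=0)
    per_vertex[~finite] = -np.inf
    v_star = int(per_vertex.argmax())
    mu = float(per_vertex[v_star])
    # Walk parent edges back from (n, v_star). walk[i] is the vertex at DP
    # level n - i; the first repeated vertex closes a cycle, and every cycle
    # on an optimal walk to v_star has mean exactly mu.
    walk = [v_star]
    pos = {v_star: 0}
    v, step = v_star, n
    cycle = None
    while step > 0:
        eidx = int(P[step][v])
        if eidx < 0:
            break
        u = int(eu[eidx])
        step -= 1
        if u in pos:
            j = pos[u]
            # forward order: u, walk[-1], walk[-2], ..., walk[j + 1]
            cycle = [u] + walk[:j:-1]
            break
        walk.append(u)
        pos[u] = len(walk) - 1
        v = u
    if cycle is None:
        return None, None
    return mu, cycle


def has_cycle(counts: dict[str, int]) -> bool:
    """True iff the de Bruijn graph of these k-mers contains a cycle (Kahn)."""
    indeg: dict[str, int] = {}
    out: dict[str, list[str]] = {}
    for km in counts:
        u, v = km[:-1], km[1:]
        out.setdefault(u, []).append(v)
        indeg[v] = indeg.get(v, 0) + 1
        indeg.setdefault(u, indeg.get(u, 0))
    queue = [n for n, d in indeg.items() if d == 0]
    removed = 0
    while queue:
        u = queue.pop()
        removed += 1
        for v in out.get(u, ()):
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    return removed < len(indeg)


def greedy_heavy_cycle(kept: dict[str, int]) -> str | None:
    """Heaviest-walk cycle: follow the locally heaviest unvisited arc.

    Complements the exact max-mean cycle: on diverged clusters the mean
    objective can be lured onto a short 'conserved stretch + coincidental
    jump' cycle, whereas the local-majority walk keeps to the full monomer.
    Starts from the globally heaviest arc; returns the cycle sequence or
    None when the walk dead-ends without closing.
    """
    if not kept:
        return None
    adj: dict[str, list[tuple[int, str]]] = {}
    for km, w in kept.items():
        adj.setdefault(km[:-1], []).append((w, km))
    for u in adj:
        adj[u].sort(key=lambda t: (-t[0], t[1]))
    heaviest = max(kept, key=lambda km: (kept[km], km))
    start = heaviest[:-1]
    path_kmers: list[str] = []
    pos = {start: 0}
    tried: list[int] = [0]  # arc index attempted at each path node
    u = start
    budget = 200_000
    while budget > 0:
        budget -= 1
        arcs = adj.get(u, ())
        idx = tried[-1]
        if idx >= len(arcs):
            # dead end: backtrack one step and try the next-heaviest arc
            if not path_kmers:
                return None
            km = path_kmers.pop()
            pos.pop(km[1:], None)
            tried.pop()
            u = km[:-1]
            continue
        _, km = arcs[idx]
        v = km[1:]
        if v in pos:
            # heaviest arc re-enters the walk: the majority path has come
            # full circle - return the cycle part
            cycle_kmers = path_kmers[pos[v]:] + [km]
            return "".join(x[-1] for x in cycle_kmers)
        path_kmers.append(km)
        pos[v] = len(path_kmers)
        tried[-1] += 1
        tried.append(0)
        u = v
    return None


def _pruned(counts: dict[str, int], prune_frac: float = 0.1,
            max_nodes: int = 3000) -> dict[str, int]:
    """Drop light (error / private-variant) k-mers; raise the cut until the
    graph fits the quadratic-DP node budget."""
    max_w = max(counts.values())
    thr = max(1, int(round(prune_frac * max_w)))
    kept = {km: w for km, w in counts.items() if w >= thr}
    while len(kept) > 2 * max_nodes and thr < max_w:
        thr += 1
        kept = {km: w for km, w in kept.items() if w >= thr}
    return kept


def _cycle_from_counts(counts: dict[str, int], k: int, prune_frac: float = 0.1,
                       max_nodes: int = 3000):
    """Best de Bruijn cycle from k-mer counts.

    Light (error / private-variant) edges below ``prune_frac`` of the maximum
    weight are removed before the exact max-mean-cycle search; the threshold
    is raised further if the graph still exceeds ``max_nodes`` (the DP is
    quadratic in node count). Returns ``(cycle_weight, cycle_sequence)`` or
    ``(0.0, None)``.
    """
    if not counts:
        return 0.0, None
    kept = _pruned(counts, prune_frac, max_nodes)
    nodes: dict[str, int] = {}
    edges = []
    edge_info = []
    for km, w in kept.items():
        u, v = km[:-1], km[1:]
        for node in (u, v):
            if node not in nodes:
                nodes[node] = len(nodes)
        edges.append((nodes[u], nodes[v], float(w)))
        edge_info.append((nodes[u], nodes[v], km, w))
    mu, cycle = max_mean_weight_cycle(edges, len(nodes))
    if cycle is None or len(cycle) == 0:
        return 0.0, None
    # sequence: last base of each k-mer edge along the cycle
    lookup = {(u, v): (km, w) for u, v, km, w in edge_info}
    seq_chars = []
    weight = 0.0
    m = len(cycle)
    for i in range(m):
        u, v = cycle[i], cycle[(i + 1) % m]
        km, w = lookup.get((u, v), (None, 0))
        if km is None:
            return 0.0, None
        seq_chars.append(km[-1])
        weight += counts[km]
    return weight, "".join(seq_chars)


def cycle_weight_fraction(seqs: list[str], k_db: int = 21) -> tuple[float, str | None]:
    """Fraction of de Bruijn k-mer weight lying on the best monomer cycle.

    Both strands of every read contribute, so total weight is halved to count
    each read once; clipped to [0, 1]. This is the raw graph-topology
    statistic: it is exact for young, homogeneous tandems but decays with
    intra-family divergence (every private mutation spawns off-cycle k-mers).
    """
    counts = build_debruijn(seqs, k_db)
    total = sum(counts.values()) / 2.0
    if total <= 0:
        return 0.0, None
    weight, cycle_seq = _cycle_from_counts(counts, k_db)
    return min(1.0, weight / total), cycle_seq


def _score_cycle(cycle_seq: str, seqs: list[str], align_identity: float):
    """(aligned fraction, mean identity) of cluster reads vs a cycle tandem.

    The fraction counts read bp whose best infix identity against a tandem
    of the cycle reaches ``align_identity``; the mean identity over all
    cluster reads discriminates between a full-length monomer and a
    truncated near-cycle (reads covering the missing stretch drag it down).
    """
    L = len(cycle_seq)
    doubled = cycle_seq + cycle_seq
    if L < max(len(s) for s in seqs):
        # short monomer: repeat it so a full read always fits a tandem window
        doubled = cycle_seq * (2 + max(len(s) for s in seqs) // L)
    targets = (doubled, revcomp(doubled))
    aligned_bp = 0
    ident_sum = 0.0
    junction_reads = 0
    for s in seqs:
        best = None
        for t in targets:
            res = edlib.align(s, t, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], res["locations"][0], t)
        if best is None:
            continue
        ident = max(0.0, 1.0 - best[0] / len(s))
        ident_sum += ident
        if ident >= align_identity:
            aligned_bp += len(s)
            lo, hi = best[1]
            if lo // L != hi // L and _spans_junction(s, best[2], L, align_identity):
                junction_reads += 1
    return aligned_bp / sum(len(s) for s in seqs), ident_sum / len(seqs), junction_reads


def _spans_junction(read: str, target: str, L: int, min_side_identity: float,
                    margin: int = 35) -> bool:
    """True if the read matches the tandem well on BOTH sides of a junction.

    A read from a genuine tandem matches across any monomer boundary; a read
    running past the closing repeat of a 'lasso' cycle matches only up to
    the junction, so its far side scores near background identity.
    """
    res = edlib.align(read, target, mode="HW", task="path")
    if res["editDistance"] < 0:
        return False
    nice = edlib.getNiceAlignment(res, read, target)
    tpos = res["locations"][0][0]
    sides: dict[int, list[int]] = {}
    for qa, ta in zip(nice["query_aligned"], nice["target_aligned"]):
        if ta != "-":
            block = tpos // L
            m, n = sides.setdefault(block, [0, 0])
            if qa == ta:
                sides[block][0] += 1
            sides[block][1] += 1
            tpos += 1
    good = [b for b, (m, n) in sides.items() if n >= margin and m / n >= min_side_identity]
    return len(good) >= 2 and any(b + 1 in good for b in good)


def circularity_score(cluster: ReadCluster, reads: list[str], k_db: int = 21,
                      align_identity: float = 0.70,
                      k_db_ladder: tuple = (41, 31, 21, 13)):
    """How tandem-like a cluster is, in [0, 1].

    A consensus cycle candidate is extracted from the cluster's de Bruijn
    graph at each word size of the ladder (exact max-mean cycle plus the
    greedy majority walk); every candidate is scored by aligning the cluster
    reads back to a tandem of it, and the candidate with the best mean read
    identity (then aligned fraction, then length) wins. The returned score
    is the winning candidate's aligned-bp fraction at >= ``align_identity``;
    a cluster with no cycle at any word size - e.g. a single-copy locus
    whose reads tile into a path - scores 0. Aligning reads rather than
    counting on-cycle k-mer weight keeps the score high for genuinely tandem
    clusters whose units have diverged (a 10%-diverged unit shares almost no
    exact 21-mers with the consensus yet still aligns to it).
    """
    seqs = [reads[i] for i in cluster.read_ids]
    ks = list(dict.fromkeys([*(k_db_ladder or ()), k_db]))
    best = None  # (mean identity, fraction, length, sequence, junction reads)
    for k in sorted(ks, reverse=True):
        counts = build_debruijn(seqs, k)
        if not counts or not has_cycle(counts):
            continue
        _, karp_cycle = _cycle_from_counts(counts, k)
        candidates = {c for c in (karp_cycle, greedy_heavy_cycle(counts)) if c}
        for cycle_seq in sorted(candidates):
            frac, mean_ident, junctions = _score_cycle(cycle_seq, seqs, align_identity)
            key = (mean_ident, frac, len(cycle_seq), cycle_seq, junctions)
            if best is None or key[:4] > best[:4]:
                best = key
        # a clean, well-supported cycle at a long word size is final; only
        # degraded outcomes fall through to shorter words
        if best is not None and best[0] >= 0.90 and best[1] >= 0.5:
            break
    if best is None:
        cluster.circularity = 0.0
        cluster.consensus_cycle = None
        return 0.0
    cluster.circularity = best[1]
    cluster.consensus_cycle = best[3]
    cluster.junction_reads = best[4]
    return best[1]


def polish_consensus(cycle_seq: str, seqs: list[str], min_identity: float = 0.70) -> str:
    """Per-position majority vote of cluster reads over the cycle sequence.

    Reads are aligned end-gap-free to a tandem of the cycle (either strand);
    matched columns vote on the corresponding monomer position (mod unit
    length). Substitution-only polishing, so the unit length is preserved.
    """
    L = len(cycle_seq)
    reps = max(3, 1 + max(len(s) for s in seqs) // L + 1)
    targets = {"+": cycle_seq * reps, "-": revcomp(cycle_seq * reps)}
    votes = np.zeros((L, 4), dtype=np.int32)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for read in seqs:
        best = None
        for strand, target in targets.items():
            res = edlib.align(read, target, mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], strand, res, target)
        if best is None:
            continue
        dist, strand, res, target = best
        if 1 - dist / len(read) < min_identity:
            continue
        nice = edlib.getNiceAlignment(res, read, target)
        tpos = res["locations"][0][0]
        comp = str.maketrans("ACGT", "TGCA")
        for qa, ta in zip(nice["query_aligned"], nice["target_aligned"]):
            if ta == "-":
                continue
            if qa != "-" and qa in base_idx:
                if strand == "+":
                    pos, base = tpos % L, qa
                else:
                    pos, base = (len(target) - 1 - tpos) % L, qa.translate(comp)
                votes[pos, base_idx[base]] += 1
            tpos += 1
    out = list(cycle_seq)
    for i in range(L):
        if votes[i].sum() > 0:
            out[i] = "ACGT"[int(votes[i].argmax())]
    return "".join(out)


def _collapse_multimer(seq: str, seqs_cluster: list[str], cfg: "MiningConfig") -> str:
    """Collapse a consensus that is really a tandem multimer of its unit.

    When two diverged neighbouring units share a long exact word, the cycle
    can close after two (or more) units instead of one; after polishing,
    every period of such a multimer converges to the same consensus, so the
    multimer and its subunit explain the reads equally well. The shortest
    period whose polished subunit matches the reads essentially as well as
    the full cycle (within ``tie_margin`` mean identity) is therefore
    reported - the fundamental repeat. A genuine long monomer with internal
    subrepeats survives: its reads match the full unit far better than any
    single subunit.
    """
    from .monomer import find_direct_subrepeats

    tie_margin = 0.01
    _, best_mean, _ = _score_cycle(seq, seqs_cluster, cfg.circ_align_identity)
    candidates = [
        sub for sub in find_direct_subrepeats(seq, min_period=cfg.min_monomer,
                                              min_identity=0.8)
        if sub.fraction_of_monomer >= 0.95
    ]
    for sub in sorted(candidates, key=lambda s: s.period):
        cand = polish_consensus(seq[:sub.period], seqs_cluster, cfg.circ_align_identity)
        _, mean_c, _ = _score_cycle(cand, seqs_cluster, cfg.circ_align_identity)
        if mean_c >= best_mean - tie_margin:
            return cand
    return seq


def build_consensus(cluster: ReadCluster, reads: list[str], round_index: int = 1,
                    cfg: MiningConfig | None = None) -> ConsensusMonomer | None:
    """Monomer consensus: best de Bruijn cycle polished by read majority vote.

    Requires circularity above the configured threshold (computed on demand);
    cycles shorter than ``min_monomer`` are rejected. The consensus is
    reported in canonical rotation so family identity is stable across runs.
    """
    cfg = cfg or MiningConfig()
    if cluster.circularity is None:
        circularity_score(cluster, reads, cfg.k_db, cfg.circ_align_identity,
                          cfg.k_db_ladder)
    if cluster.consensus_cycle is None:
        return None
    seq = cluster.consensus_cycle
    if len(seq) < cfg.min_monomer:
        logger.info("cycle of %d bp below min_monomer, rejected", len(seq))
        return None
    seqs_cluster = [reads[i] for i in cluster.read_ids]
    seq = polish_consensus(seq, seqs_cluster, cfg.circ_align_identity)
    seq = _collapse_multimer(seq, seqs_cluster, cfg)
    return ConsensusMonomer(
        name="",
        sequence=canonical_rotation(seq),
        unit_length=len(seq),
        n_reads=len(cluster.read_ids),
        round_index=round_index,
        circularity=cluster.circularity,
        genome_proportion=cluster.genome_proportion,
        low_confidence=cluster.circularity < cfg.circ_threshold,
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _read_matches_monomer(read: str, doubled_targets: list[str], kmer_sets: list[set],
                          cfg: MiningConfig) -> bool:
    half = len(read) // 2
    probe = set()
    for i in range(0, len(read) - 11 + 1, 4):
        probe.add(read[i:i + 11])
    for target, kms in zip(doubled_targets, kmer_sets):
        if kms is not None and len(probe & kms) < 1:
            continue
        if infix_identity(read, target) >= cfg.filter_identity:
            return True
        if cfg.filter_coverage <= 0.5 and half >= 20:
            if (infix_identity(read[:half], target) >= cfg.filter_identity
                    or infix_identity(read[half:], target) >= cfg.filter_identity):
                return True
    return False


def _monomer_targets(monomers: list[ConsensusMonomer] | list[str]):
    targets, kmer_sets = [], []
    for mon in monomers:
        seq = mon.sequence if isinstance(mon, ConsensusMonomer) else mon
        for t in (seq + seq, revcomp(seq + seq)):
            targets.append(t)
            kms = {t[i:i + 11] for i in range(len(t) - 10)}
            kmer_sets.append(kms)
    return targets, kmer_sets


def filter_reads(pairs: list, monomers, cfg: MiningConfig | None = None) -> list:
    """Drop every read pair in which either mate matches a known monomer.

    A mate matches when it aligns to the doubled monomer (either strand) at
    identity >= ``filter_identity`` over >= ``filter_coverage`` of its length.
    """
    cfg = cfg or MiningConfig()
    if not monomers:
        return list(pairs)
    targets, kmer_sets = _monomer_targets(monomers)
    kept = []
    for pair in pairs:
        if _read_matches_monomer(pair.seq1, targets, kmer_sets, cfg) or \
           _read_matches_monomer(pair.seq2, targets, kmer_sets, cfg):
            continue
        kept.append(pair)
    return kept


def rotational_percent_identity(a: str, b: str) -> float:
    """Best percent identity of a vs all rotations/strands of b (for dedup)."""
    from .compare_map import rotational_alignment

    return rotational_alignment(a, b).identity


@dataclass
class RoundSummary:
    round_index: int
    sampled_pairs: int
    n_clusters: int
    n_new_monomers: int
    library_size_after: int
    clusters: list[dict] = field(default_factory=list)


def run_satminer(pairs: list, n_rounds: int = 3, pairs_per_round: int | None = None,
                 seed: int = 0, cfg: MiningConfig | None = None):
    """The full iterative discovery loop.

    Returns ``(monomers, round_summaries)``. Monomers are deduplicated by
    rotational identity and named ``FamNN-<len>`` in order of discovery
    (renamed by abundance at catalog time).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    cfg = cfg or MiningConfig()
    library = list(pairs)
    monomers: list[ConsensusMonomer] = []
    summaries: list[RoundSummary] = []
    rng = np.random.default_rng(seed)
    for rnd in range(1, n_rounds + 1):
        if not library:
            logger.info("library exhausted before round %d", rnd)
            break
        n_sample = min(pairs_per_round or len(library), len(library))
        sample = sample_reads(library, n_sample, int(rng.integers(2**31)))
        reads = [s for p in sample for s in (p.seq1, p.seq2)]
        total_bp = sum(len(r) for r in reads)
        graph = build_similarity_graph(reads, cfg=cfg)
        clusters = cluster_reads(graph, reads, total_bp, cfg.min_cluster_size)
        new_monomers = []
        cluster_rows = []
        for ci, cluster in enumerate(clusters):
            score = circularity_score(cluster, reads, cfg.k_db,
                                      cfg.circ_align_identity, cfg.k_db_ladder)
            cluster_rows.append(
                {"round": rnd, "cluster": ci, "n_reads": len(cluster.read_ids),
                 "genome_proportion": cluster.genome_proportion, "circularity": score}
            )
            if score < cfg.circ_threshold:
                continue
            mon = build_consensus(cluster, reads, rnd, cfg)
            if mon is None:
                continue
            cluster_bp = sum(len(reads[i]) for i in cluster.read_ids)
            if score * cluster_bp / mon.unit_length < cfg.min_cycle_coverage:
                logger.info("cycle of %d bp covered < %.1fx, rejected",
                            mon.unit_length, cfg.min_cycle_coverage)
                continue
            if cluster.junction_reads < cfg.min_junction_reads:
                logger.info("cycle of %d bp lacks junction-spanning reads, rejected",
                            mon.unit_length)
                continue
            if any(
                rotational_percent_identity(mon.sequence, known.sequence) >= cfg.dedup_identity
                for known in monomers + new_monomers
            ):
                continue
            new_monomers.append(mon)
        for mon in new_monomers:
            mon.name = f"Fam{len(monomers) + 1:02d}-{mon.unit_length}"
            monomers.append(mon)
        if new_monomers:
            library = filter_reads(library, new_monomers, cfg)
        summaries.append(
            RoundSummary(rnd, n_sample, len(clusters), len(new_monomers), len(library),
                         cluster_rows)
        )
    return monomers, summaries
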