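"""Brute-force enumeration oracles, independent of the library implementations."""

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_subrepeats(seq, min_period=3, min_identity=0.6, min_copies=2):
    """Plain-loop circular period scan (independent of the numpy path)."""
    L = len(seq)
    out = []
    for p in range(min_period, L // 2 + 1):
        copies = L // p
        if copies < min_copies:
            continue
        agree = 0
        for col in range(p):
            counts = {}
            for row in range(copies):
                b = seq[(row * p + col) % L]
                counts[b] = counts.get(b, 0) + 1
            agree += max(counts.values())
        ident = agree / (p * copies)
        if ident >= min_identity:
            out.append((p, copies, ident))
    return out


def brute_inverted(seq, min_stem=5, max_loop=100, max_mismatch=0):
    """Enumerate every (left_start, right_start, stem) triple; keep maximal."""
    L = len(seq)
    hits = []
    for ls in range(L):
        for rs in range(ls + 1, L):
            max_stem = min(rs - ls, L - rs)
            for stem in range(min_stem, max_stem + 1):
                loop = rs - (ls + stem)
                if loop < 0 or loop > max_loop:
                    continue
                mism = sum(
                    1 for s in range(stem)
                    if COMP[seq[ls + stem - 1 - s]] != seq[rs + s]
                )
                if mism > max_mismatch:
                    continue
                # maximal: innermost pair matches, not outward-extendable
                if COMP[seq[ls + stem - 1]] != seq[rs]:
                    continue
                if ls > 0 and rs + stem < L and COMP[seq[ls - 1]] == seq[rs + stem] \
                        and mism <= max_mismatch:
                    continue
                hits.append((ls, rs, stem))
    # containment suppression (same rule as the implementation)
    kept = []
    for h in sorted(hits, key=lambda t: -t[2]):
        ls, rs, stem = h
        if not any(
            k[0] <= ls and ls + stem <= k[0] + k[2]
            and k[1] <= rs and rs + stem <= k[1] + k[2]
            for k in kept
        ):
            kept.append(h)
    return sorted(kept)


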