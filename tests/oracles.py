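"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid dynamic programming and closed-form shortcuts:
the alignment oracle enumerates every glocal alignment path, and the
hypergeometric oracle counts combinations explicitly.
"""

from itertools import combinations


def brute_force_glocal_score(query, target, scheme):
    """Maximum score over all alignments consuming the whole query and
    any contiguous target substring, by exhaustive path enumeration.

    Gap runs cost gap_open for their first residue and gap_extend for
    each additional one. Leading/trailing target residues are free.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(query), len(target)
    best = float("-inf")

    def rec(i, j, prev, acc):
        nonlocal best
        if i == n:
            # remaining target residues are a free trailing skip
            if acc > best:
                best = acc
            return
        if j < m:
            rec(i + 1, j + 1, "D", acc + scheme.score(query[i], target[j]))
        rec(i + 1, j, "P", acc + (ge if prev == "P" else go))
        if j < m:
            rec(i, j + 1, "Q", acc + (ge if prev == "Q" else go))

    for start in range(m + 1):  # free leading skip
        rec(0, start, None, 0)
    return int(best)


def hypergeom_upper_tail(N, K, n, k):
    """P[X >= k] for X ~ Hypergeometric(N, K, n) by enumerating all
    C(N, n) equally likely draws from a population with K marked items."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            hits += 1
    return hits / total
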