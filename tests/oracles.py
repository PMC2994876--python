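"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by exhaustive search or direct summation,
deliberately avoiding the algorithms used in the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from srnakit.folding import MIN_HAIRPIN, score_structure

_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"),
}


def enumerate_structures(seq: str):
    """Yield every nested pair set (allowed pairs, hairpin loops >= 3)."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    def can_pair(i: int, j: int) -> bool:
        return j - i - 1 >= MIN_HAIRPIN and (seq[i], seq[j]) in _PAIRABLE

    def gen(i: int, j: int):
        # all structures on region [i, j]
        if i >= j:
            yield []
            return
        # base i unpaired
        yield from gen(i + 1, j)
        # base i paired with some k
        for k in range(i + 1, j + 1):
            if not can_pair(i, k):
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield [(i, k)] + inner + outer

    yield from gen(0, n - 1)


def brute_force_mfe_small(seq: str) -> float:
    """MFE by scoring every enumerated structure (feasible up to ~20 nt)."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = score_structure(seq, pairs)
        if e < best:
            best = e
    return best


def brute_force_mfe(seq: str) -> float:
    """Exhaustive-enumeration MFE under the package energy model.

    Every nested structure is a tree of loops; the search enumerates, for each
    closing pair, every tiling of its interior by child helices and takes the
    loop energy straight from the model's loop definition (no V/WM recursion,
    no two-loop/multiloop case split in the search itself).  Memoizing the
    minimum over each closed region keeps full 30-nt sequences tractable while
    still covering every structure; agreement with the plain per-structure
    scorer is asserted separately at small n.
    """
    from functools import lru_cache

    from srnakit.folding import (
        ML_BRANCH, ML_CLOSE, ML_UNPAIRED, bulge_energy, hairpin_energy,
        internal_energy,
    )
    from srnakit.folding import _PAIR_IDX, _STACK, encode  # model tables

    s = encode(seq)
    n = len(s)
    INF = 1e9

    def pairable(i: int, j: int) -> bool:
        return j - i - 1 >= MIN_HAIRPIN and _PAIR_IDX[s[i], s[j]] >= 0

    def tilings(i: int, j: int):
        """Yield every set of disjoint candidate child spans in [i, j]."""
        if i > j:
            yield ()
            return
        yield from tilings(i + 1, j)
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if pairable(i, k):
                for rest in tilings(k + 1, j):
                    yield ((i, k),) + rest

    def loop_energy(i: int, j: int, children) -> float:
        if not children:
            return hairpin_energy(j - i - 1)
        if len(children) == 1:
            (a, b), = children
            l1, l2 = a - i - 1, j - b - 1
            if l1 == 0 and l2 == 0:
                return float(_STACK[_PAIR_IDX[s[i], s[j]], _PAIR_IDX[s[a], s[b]]])
            if l1 == 0 or l2 == 0:
                return bulge_energy(l1 + l2)
            return internal_energy(l1 + l2)
        unpaired = (j - i - 1) - sum(b - a + 1 for a, b in children)
        return ML_CLOSE + ML_BRANCH * (len(children) + 1) + ML_UNPAIRED * unpaired

    @lru_cache(maxsize=None)
    def best_closed(i: int, j: int) -> float:
        best = INF
        for children in tilings(i + 1, j - 1):
            sub = sum(best_closed(a, b) for a, b in children)
            if sub >= INF:
                continue
            e = loop_energy(i, j, children) + sub
            if e < best:
                best = e
        return best

    best = 0.0
    for exterior in tilings(0, n - 1):
        e = sum(best_closed(a, b) for a, b in exterior)
        if e < best:
            best = e
    return best


def brute_force_map(tag: str, genome: dict[str, str], max_mismatch: int = 2):
    """All ungapped placements of ``tag`` with <= max_mismatch mismatches.

    Scans every offset on both strands with a per-base Python comparison.
    Returns a set of (chrom, start, strand, mismatches) in forward coords.
    """
    comp = str.maketrans("ACGT", "TGCA")
    rc = tag.translate(comp)[::-1]
    hits = set()
    L = len(tag)
    for chrom, seq in genome.items():
        for start in range(len(seq) - L + 1):
            window = seq[start:start + L]
            for query, strand in ((tag, "+"), (rc, "-")):
                mm = sum(1 for a, b in zip(query, window) if a != b or a not in "ACGT")
                if mm <= max_mismatch:
                    hits.add((chrom, start, strand, mm))
    return hits


def _summation_tails(x: int, y: int, r: float) -> tuple[float, float]:
    """Naive-summation tails of p(k | x) = C(x+k, k) r^k / (1+r)^(x+k+1)."""
    q = r / (1.0 + r)

    def term(k: int) -> float:
        return math.comb(x + k, k) * q**k * (1.0 / (1.0 + r)) ** (x + 1)

    lower = sum(term(k) for k in range(y + 1))
    # upper tail summed upward with a multiplicative recurrence (the naive
    # 1 - lower form loses the tail to cancellation when it is tiny)
    upper = t = term(y)
    k = y
    while t > upper * 1e-25 or k < y + 20 or k < (x + 1) * r:
        t *= q * (x + k + 1) / (k + 1)
        upper += t
        k += 1
        if k > y + 1_000_000:
            break
    return min(lower, 1.0), min(upper, 1.0)


def bayes_pvalue_by_summation(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided digital-expression P by naive term-by-term summation,
    doubling the smallest of the four tails (both conditional directions)."""
    tails = _summation_tails(x, y, n2 / n1) + _summation_tails(y, x, n1 / n2)
    return min(1.0, 2.0 * min(tails))


def brute_force_consensus(sets: dict[str, set[tuple[str, str]]], min_support: int):
    """Consensus (miRNA, gene) pairs by direct counting over all pairs."""
    all_pairs = set(itertools.chain.from_iterable(sets.values()))
    out = {}
    for pair in all_pairs:
        support = sum(1 for pairs in sets.values() if pair in pairs)
        if support >= min_support:
            out[pair] = support
    return out


def hypergeom_tail_by_enumeration(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws (small N only)."""
    universe = list(range(big_n))
    inset = set(range(big_k))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g in inset) >= k:
            hits += 1
    return hits / total


def numpy_window_scan(tag: str, genome: dict[str, str], max_mismatch: int = 2):
    """Vectorised exhaustive-offset scan (fast oracle for larger genomes)."""
    comp = str.maketrans("ACGT", "TGCA")
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    hits = set()
    L = len(tag)
    for chrom, seq in genome.items():
        g = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if len(g) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, L)
        for query, strand in ((tag, "+"), (tag.translate(comp)[::-1], "-")):
            q = lut[np.frombuffer(query.encode(), dtype=np.uint8)]
            mm = np.sum((windows != q) | (windows < 0), axis=1)
            for start in np.nonzero(mm <= max_mismatch)[0]:
                hits.add((chrom, int(start), strand, int(mm[start])))
    return hits
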