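"""Ungapped mapping of 18-30 nt tags with a mismatch budget.

The contract is exhaustive: every placement on either strand with at most
``max_mismatch`` mismatches is reported, in forward coordinates.  The search
uses the pigeonhole principle — a tag is split into ``max_mismatch + 1``
disjoint seed chunks, so any qualifying placement contains at least one exact
chunk — with seeds resolved through per-k k-mer position indexes built lazily
on the genome, then verified base by base.  Reference positions outside ACGT
never match.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

DEFAULT_MAX_MISMATCH = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Alignment:
    """One ungapped placement of a tag (forward-strand coordinates)."""

    chrom: str
    start: int
    strand: str
    mismatches: int


class GenomeIndex:
    """Exact k-mer position lookup over both implicit strands of a genome.

    Reverse-strand hits are produced by querying the reverse complement of
    the tag against the forward sequence, so all coordinates stay forward.
    """

    def __init__(self, genome: dict[str, str]):
        if not genome:
            raise ValueError("genome is empty")
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self._kmer_index: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._kmer_index:
            index: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for chrom, seq in self.genome.items():
                for pos in range(len(seq) - k + 1):
                    kmer = seq[pos : pos + k]
                    if "N" not in kmer and set(kmer) <= set("ACGT"):
                        index[kmer].append((chrom, pos))
            self._kmer_index[k] = dict(index)
        return self._kmer_index[k]

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index_for(len(kmer)).get(kmer, [])


def _count_mismatches(query: str, reference: str, budget: int) -> int:
    mm = 0
    for a, b in zip(query, reference):
        if a != b or b not in "ACGT":
            mm += 1
            if mm > budget:
                return mm
    return mm


def map_tag(
    tag: str, index: GenomeIndex, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> list[Alignment]:
    """All ungapped placements of ``tag`` with <= max_mismatch mismatches.

    Agrees with an exhaustive per-offset scan (see the test-suite oracle) on
    both strands; results are sorted and duplicate-free.
    """
    length = len(tag)
    n_chunks = max_mismatch + 1
    k = length // n_chunks
    if k < 4:
        raise ValueError(f"tag too short to seed with {max_mismatch} mismatches")
    hits: set[Alignment] = set()
    for strand, query in (("+", tag), ("-", reverse_complement(tag))):
        seen_starts: set[tuple[str, int]] = set()
        for chunk in range(n_chunks):
            offset = chunk * k
            for chrom, pos in index.seed_hits(query[offset : offset + k]):
                start = pos - offset
                if start < 0 or start + length > len(index.genome[chrom]):
                    continue
                if (chrom, start) in seen_starts:
                    continue
                seen_starts.add((chrom, start))
                ref = index.genome[chrom][start : start + length]
                mm = _count_mismatches(query, ref, max_mismatch)
                if mm <= max_mismatch:
                    hits.add(Alignment(chrom, start, strand, mm))
    return sorted(hits)
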