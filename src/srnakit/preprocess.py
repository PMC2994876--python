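"""Read cleaning and tag collapsing.

The fixed stage order is quality filter -> 3' adapter trim -> 18-30 nt length
filter -> collapse identical inserts into counted unique tags.  Each stage
partitions its input exactly (retained + discarded = input) and the discard
tally is reported per library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import FastqRead

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30

DEFAULT_MAX_N = 0
DEFAULT_MIN_MEAN_QUALITY = 20.0
DEFAULT_MIN_ADAPTER_OVERLAP = 8


@dataclass
class DiscardTally:
    """Per-stage read accounting; stages partition their input exactly."""

    input: int = 0
    low_quality: int = 0
    no_adapter: int = 0
    out_of_length_range: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "low_quality": self.low_quality,
            "no_adapter": self.no_adapter,
            "out_of_length_range": self.out_of_length_range,
            "retained": self.retained,
        }


def quality_filter(
    reads: Iterable[FastqRead],
    max_n: int = DEFAULT_MAX_N,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
) -> tuple[list[FastqRead], int]:
    """Retain reads with <= max_n N bases and mean Phred >= threshold.

    Both boundaries are inclusive: a read whose mean quality sits exactly at
    the threshold is kept.  Returns (retained, n_discarded).
    """
    kept: list[FastqRead] = []
    discarded = 0
    for read in reads:
        n_count = read.sequence.count("N")
        mean_q = sum(read.qualities) / len(read.qualities) if read.qualities else 0.0
        if n_count <= max_n and mean_q >= min_mean_quality:
            kept.append(read)
        else:
            discarded += 1
    return kept, discarded


def trim_adapter(
    sequence: str, adapter3: str, min_overlap: int = DEFAULT_MIN_ADAPTER_OVERLAP
) -> str | None:
    """Insert before the leftmost 3' adapter occurrence, or None.

    A mid-read occurrence must match the full adapter; at the read end a
    prefix of the adapter of length >= min_overlap counts as evidence.  Reads
    without adapter evidence return None and are excluded from tag building.
    """
    if not adapter3:
        raise ValueError("adapter sequence must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    full = sequence.find(adapter3)
    candidates = []
    if full >= 0:
        candidates.append(full)
    # longest adapter prefix terminating the read = leftmost partial position
    max_ov = min(len(adapter3) - 1, len(sequence))
    for overlap in range(max_ov, min_overlap - 1, -1):
        if sequence.endswith(adapter3[:overlap]):
            candidates.append(len(sequence) - overlap)
            break
    if not candidates:
        return None
    return sequence[: min(candidates)]


def length_filter(
    inserts: Sequence[str], min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN
) -> tuple[list[str], int]:
    """Keep inserts with min_len <= length <= max_len (endpoints inclusive)."""
    kept = [s for s in inserts if min_len <= len(s) <= max_len]
    return kept, len(inserts) - len(kept)


def collapse_tags(
    inserts_lib1: Sequence[str], inserts_lib2: Sequence[str]
) -> pd.DataFrame:
    """Collapse identical insert sequences into one counted tag per sequence.

    Output rows are ordered by descending total count, ties lexicographic;
    per-library counts sum to the per-library retained totals.
    """
    c1 = Counter(inserts_lib1)
    c2 = Counter(inserts_lib2)
    sequences = sorted(
        set(c1) | set(c2), key=lambda s: (-(c1[s] + c2[s]), s)
    )
    return pd.DataFrame(
        {
            "sequence": sequences,
            "count_lib1": [c1[s] for s in sequences],
            "count_lib2": [c2[s] for s in sequences],
        }
    )


@dataclass
class PreprocessResult:
    tags: pd.DataFrame
    tally_lib1: DiscardTally = field(default_factory=DiscardTally)
    tally_lib2: DiscardTally = field(default_factory=DiscardTally)

    @property
    def report(self) -> pd.DataFrame:
        rows = []
        for lib, tally in (("lib1", self.tally_lib1), ("lib2", self.tally_lib2)):
            for stage, count in tally.as_dict().items():
                rows.append({"library": lib, "stage": stage, "reads": count})
        return pd.DataFrame(rows)


def clean_library(
    reads: Iterable[FastqRead],
    adapter3: str,
    max_n: int = DEFAULT_MAX_N,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    min_overlap: int = DEFAULT_MIN_ADAPTER_OVERLAP,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> tuple[list[str], DiscardTally]:
    """Run quality -> trim -> length on one library; return inserts + tally."""
    reads = list(reads)
    tally = DiscardTally(input=len(reads))
    passed, tally.low_quality = quality_filter(reads, max_n, min_mean_quality)
    inserts = []
    for read in passed:
        insert = trim_adapter(read.sequence, adapter3, min_overlap)
        if insert is None:
            tally.no_adapter += 1
        else:
            inserts.append(insert)
    kept, tally.out_of_length_range = length_filter(inserts, min_len, max_len)
    tally.retained = len(kept)
    return kept, tally


def preprocess_libraries(
    reads_lib1: Iterable[FastqRead],
    reads_lib2: Iterable[FastqRead],
    adapter3: str,
    **kwargs,
) -> PreprocessResult:
    inserts1, tally1 = clean_library(reads_lib1, adapter3, **kwargs)
    inserts2, tally2 = clean_library(reads_lib2, adapter3, **kwargs)
    tags = collapse_tags(inserts1, inserts2)
    return PreprocessResult(tags=tags, tally_lib1=tally1, tally_lib2=tally2)
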