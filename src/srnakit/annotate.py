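"""Hierarchical classification of mapped tags.

Each tag is mapped (<= 2 mismatches, both strands) and assigned the first
category its placements touch in the priority cascade
miRNA > ncRNA > repeat > mRNA; mapped tags touching no annotation are
"unclassified" and unmapped tags "unmapped".  A placement counts as a
category hit when at least half of the tag's bases fall inside an interval
of that category on the same strand (repeats are strand-agnostic).  Tags
overlapping a catalogued precursor are attributed to the catalog mature
miRNA when their 5' end lies within the isomiR window of the mature 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .mapping import Alignment, GenomeIndex, map_tag

CATEGORIES = ("miRNA", "ncRNA", "repeat", "mRNA")
DEFAULT_PRIORITY = list(CATEGORIES)
DEFAULT_MIN_OVERLAP_FRACTION = 0.5
DEFAULT_ISOMIR_WINDOW = 3
MAX_REPORTED_PLACEMENTS = 20


@dataclass(frozen=True)
class AnnotationInterval:
    """0-based half-open genomic interval carrying a category label."""

    chrom: str
    start: int
    end: int
    strand: str
    category: str
    name: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.name}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} in {self.name}")


@dataclass(frozen=True)
class MatureRecord:
    """Catalog entry: mature sequence placed within its precursor."""

    name: str
    mature_sequence: str
    chrom: str
    precursor_start: int
    precursor_end: int
    mature_start: int
    mature_end: int
    strand: str
    arm: str  # 5p / 3p


@dataclass
class ClassifiedTag:
    sequence: str
    count_lib1: int
    count_lib2: int
    placements: list[Alignment]
    category: str
    matched_name: str | None = None
    placements_capped: bool = False


@dataclass
class AnnotationSet:
    """Interval trees per chromosome, plus the mature-miRNA catalog."""

    intervals: list[AnnotationInterval]
    catalog: list[MatureRecord] = field(default_factory=list)

    def __post_init__(self):
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )
        self._mature_by_precursor: dict[tuple, list[MatureRecord]] = {}
        for rec in self.catalog:
            key = (rec.chrom, rec.precursor_start, rec.precursor_end)
            self._mature_by_precursor.setdefault(key, []).append(rec)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, catalog: list[MatureRecord] | None = None):
        intervals = [
            AnnotationInterval(
                r.chrom, int(r.start), int(r.end), r.strand, r.category, str(r.name)
            )
            for r in df.itertuples(index=False)
        ]
        return cls(intervals, catalog or [])

    def overlapping(self, chrom: str, start: int, end: int):
        tree = self._trees.get(chrom)
        return [hit.data for hit in tree.overlap(start, end)] if tree else []


def _tag_five_prime(aln: Alignment, length: int) -> int:
    return aln.start if aln.strand == "+" else aln.start + length


def _mature_five_prime(rec: MatureRecord) -> int:
    return rec.mature_start if rec.strand == "+" else rec.mature_end


def classify_tag(
    sequence: str,
    count_lib1: int,
    count_lib2: int,
    placements: list[Alignment],
    annotations: AnnotationSet,
    priority: list[str] | None = None,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
    isomir_window: int = DEFAULT_ISOMIR_WINDOW,
) -> ClassifiedTag:
    """Assign a category by the priority cascade over all placements.

    The result depends only on the placement/annotation overlap set, never on
    annotation input order.
    """
    priority = priority or DEFAULT_PRIORITY
    length = len(sequence)
    capped = len(placements) > MAX_REPORTED_PLACEMENTS
    kept = placements[:MAX_REPORTED_PLACEMENTS]
    if not placements:
        return ClassifiedTag(
            sequence, count_lib1, count_lib2, [], "unmapped", None, False
        )
    touched: dict[str, list[tuple[Alignment, AnnotationInterval]]] = {}
    for aln in kept:
        for iv in annotations.overlapping(aln.chrom, aln.start, aln.start + length):
            overlap = min(aln.start + length, iv.end) - max(aln.start, iv.start)
            if overlap < min_overlap_fraction * length:
                continue
            if iv.category != "repeat" and iv.strand != aln.strand:
                continue
            touched.setdefault(iv.category, []).append((aln, iv))
    for category in priority:
        if category not in touched:
            continue
        matched = None
        if category == "miRNA":
            matched = _match_catalog(
                length, touched[category], annotations, isomir_window
            )
        return ClassifiedTag(
            sequence, count_lib1, count_lib2, kept, category, matched, capped
        )
    return ClassifiedTag(
        sequence, count_lib1, count_lib2, kept, "unclassified", None, capped
    )


def _match_catalog(length, mirna_hits, annotations, isomir_window):
    """Attribute a miRNA-category tag to a catalog mature (isomiR window)."""
    for aln, iv in mirna_hits:
        key = (iv.chrom, iv.start, iv.end)
        for rec in annotations._mature_by_precursor.get(key, []):
            if rec.strand != aln.strand:
                continue
            if abs(_tag_five_prime(aln, length) - _mature_five_prime(rec)) <= isomir_window:
                return rec.name
    return None


def annotate_tags(
    tags: pd.DataFrame,
    index: GenomeIndex,
    annotations: AnnotationSet,
    max_mismatch: int = 2,
    priority: list[str] | None = None,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
    isomir_window: int = DEFAULT_ISOMIR_WINDOW,
) -> list[ClassifiedTag]:
    """Map and classify every tag of a collapsed tag table."""
    out = []
    for row in tags.itertuples(index=False):
        placements = map_tag(row.sequence, index, max_mismatch)
        out.append(
            classify_tag(
                row.sequence,
                int(row.count_lib1),
                int(row.count_lib2),
                placements,
                annotations,
                priority,
                min_overlap_fraction,
                isomir_window,
            )
        )
    return out


def classified_frame(classified: list[ClassifiedTag]) -> pd.DataFrame:
    rows = []
    for tag in classified:
        best = min(tag.placements, key=lambda a: a.mismatches) if tag.placements else None
        rows.append(
            {
                "sequence": tag.sequence,
                "count_lib1": tag.count_lib1,
                "count_lib2": tag.count_lib2,
                "category": tag.category,
                "matched_name": tag.matched_name or "",
                "n_placements": len(tag.placements),
                "best_chrom": best.chrom if best else "",
                "best_start": best.start if best is not None else -1,
                "best_strand": best.strand if best else "",
                "best_mismatches": best.mismatches if best is not None else -1,
            }
        )
    return pd.DataFrame(rows)


def summarize_categories(
    classified: list[ClassifiedTag], weight: str = "reads"
) -> pd.DataFrame:
    """Category proportions per library over mapped reads (or unique tags).

    Proportions are taken over mapped tags only (the Fig-2B-style view); the
    mapped fraction of all retained reads is reported as a separate row with
    category 'mapped_fraction'.
    """
    if weight not in ("reads", "tags"):
        raise ValueError("weight must be 'reads' or 'tags'")
    if not classified:
        return pd.DataFrame(columns=["category", "lib1", "lib2"])
    cats = [*CATEGORIES, "unclassified"]
    totals = {"lib1": 0.0, "lib2": 0.0}
    counts = {c: {"lib1": 0.0, "lib2": 0.0} for c in cats}
    all_totals = {"lib1": 0.0, "lib2": 0.0}
    for tag in classified:
        w1, w2 = (
            (tag.count_lib1, tag.count_lib2)
            if weight == "reads"
            else (1.0 * (tag.count_lib1 > 0), 1.0 * (tag.count_lib2 > 0))
        )
        all_totals["lib1"] += w1
        all_totals["lib2"] += w2
        if tag.category == "unmapped":
            continue
        counts[tag.category]["lib1"] += w1
        counts[tag.category]["lib2"] += w2
        totals["lib1"] += w1
        totals["lib2"] += w2
    rows = [
        {
            "category": c,
            "lib1": counts[c]["lib1"] / totals["lib1"] if totals["lib1"] else 0.0,
            "lib2": counts[c]["lib2"] / totals["lib2"] if totals["lib2"] else 0.0,
        }
        for c in cats
    ]
    rows.append(
        {
            "category": "mapped_fraction",
            "lib1": totals["lib1"] / all_totals["lib1"] if all_totals["lib1"] else 0.0,
            "lib2": totals["lib2"] / all_totals["lib2"] if all_totals["lib2"] else 0.0,
        }
    )
    return pd.DataFrame(rows)


def length_distribution(
    classified: list[ClassifiedTag], weight: str = "reads"
) -> pd.DataFrame:
    """Read-weighted insert-length histogram over the 18-30 nt window."""
    lengths = range(18, 31)
    hist = {L: {"lib1": 0, "lib2": 0} for L in lengths}
    for tag in classified:
        L = len(tag.sequence)
        if L not in hist:
            continue
        w1, w2 = (
            (tag.count_lib1, tag.count_lib2)
            if weight == "reads"
            else (int(tag.count_lib1 > 0), int(tag.count_lib2 > 0))
        )
        hist[L]["lib1"] += w1
        hist[L]["lib2"] += w2
    return pd.DataFrame(
        {
            "length": list(lengths),
            "lib1": [hist[L]["lib1"] for L in lengths],
            "lib2": [hist[L]["lib2"] for L in lengths],
        }
    )


def histogram_mode(hist: pd.DataFrame, library: str) -> int:
    return int(hist.loc[hist[library].idxmax(), "length"])
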