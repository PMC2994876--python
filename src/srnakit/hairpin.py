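"""Novel miRNA discovery from unclassified mapped tags.

For each unclassified placement the genomic window of 100 nt flanking each
side of the tag is extracted (reverse-complemented for minus-strand
placements so the tag reads 5'->3'), folded, and trimmed to the stem-loop
harbouring the tag.  The trimmed precursor is refolded and must satisfy the
hairpin criteria — single stem-loop, mature wholly on one arm, >= 16 mature
bases paired, MFE <= -18 kcal/mol, precursor length 60-100 nt — before a
candidate is called.  Candidates are deduplicated by precursor interval and
partitioned into shared / library-1-only / library-2-only sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .folding import FoldResult, fold_mfe
from .io import genomic_location
from .mapping import Alignment, reverse_complement

DEFAULT_FLANK = 100


@dataclass(frozen=True)
class HairpinCriteria:
    """Acceptance rules for a candidate precursor (all config-exposed)."""

    mature_length_range: tuple[int, int] = (20, 24)
    min_paired_mature_bases: int = 16
    max_mfe: float = -18.0
    precursor_length_range: tuple[int, int] = (60, 100)
    max_stem_gap: int = 6  # max unpaired bases in one bulge/internal step
    min_total_reads: int = 5  # tag support needed to fold a candidate


@dataclass
class CandidateLocus:
    """A tag placement plus its flanking window, in tag orientation."""

    sequence: str
    count_lib1: int
    count_lib2: int
    chrom: str
    strand: str
    tag_start: int  # genomic, 0-based half-open
    tag_end: int
    window_start: int
    window_end: int
    window_sequence: str
    mature_offset: int  # tag start within the oriented window


def extract_flanks(
    sequence: str,
    count_lib1: int,
    count_lib2: int,
    placement: Alignment,
    genome: dict[str, str],
    flank: int = DEFAULT_FLANK,
) -> CandidateLocus:
    """Window of ``flank`` nt each side of the placement, clipped and oriented."""
    chrom_seq = genome[placement.chrom]
    tag_start, tag_end = placement.start, placement.start + len(sequence)
    if tag_start < 0 or tag_end > len(chrom_seq):
        raise ValueError("placement outside genome")
    w_start = max(0, tag_start - flank)
    w_end = min(len(chrom_seq), tag_end + flank)
    window = chrom_seq[w_start:w_end]
    if placement.strand == "-":
        window = reverse_complement(window)
        mature_offset = w_end - tag_end
    else:
        mature_offset = tag_start - w_start
    return CandidateLocus(
        sequence, count_lib1, count_lib2, placement.chrom, placement.strand,
        tag_start, tag_end, w_start, w_end, window, mature_offset,
    )


@dataclass
class HairpinCall:
    """An accepted novel-miRNA candidate (Table-2-style record)."""

    name: str
    mature_sequence: str
    mature_length: int
    chrom: str
    precursor_start: int  # genomic, 0-based half-open
    precursor_end: int
    strand: str
    arm: str  # 5p / 3p
    precursor_length: int
    mfe: float
    structure: str
    precursor_sequence: str
    count_lib1: int
    count_lib2: int
    rel_lib1: float = 0.0
    rel_lib2: float = 0.0
    eligible: bool = False

    @property
    def location(self) -> str:
        return genomic_location(self.chrom, self.precursor_start, self.precursor_end, self.strand)


def _children_map(pairs: list[tuple[int, int]]) -> dict[tuple[int, int] | None, list]:
    """Direct-nesting tree of a pair list (None = exterior)."""
    children: dict[tuple[int, int] | None, list] = {None: []}
    stack: list[tuple[int, int]] = []
    for pair in sorted(pairs):
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(pair)
        children.setdefault(pair, [])
        stack.append(pair)
    return children


def _stem_chains(pairs: list[tuple[int, int]], max_gap: int) -> list[list[tuple[int, int]]]:
    """Stem-loop pair chains, innermost (hairpin tip) first.

    From each hairpin tip the chain walks outward while the enclosing loop
    stays single-branched with at most ``max_gap`` unpaired bases per
    bulge/internal step."""
    children = _children_map(pairs)
    parent = {}
    for par, kids in children.items():
        for kid in kids:
            parent[kid] = par
    chains = []
    tips = [p for p in pairs if not children[p]]
    for tip in tips:
        chain = [tip]
        cur = tip
        while True:
            par = parent.get(cur)
            if par is None or len(children[par]) != 1:
                break
            gap = (cur[0] - par[0] - 1) + (par[1] - cur[1] - 1)
            if gap > max_gap:
                break
            chain.append(par)
            cur = par
        chains.append(chain)
    return chains


def _stem_loops(pairs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Maximal stem-loop spans (outermost pair of each stem chain)."""
    return [chain[-1] for chain in _stem_chains(pairs, max_gap)]


def assess_hairpin(
    locus: CandidateLocus,
    criteria: HairpinCriteria = HairpinCriteria(),
    window_fold: FoldResult | None = None,
) -> HairpinCall | str:
    """Evaluate one candidate window; returns a HairpinCall or the first
    failed criterion as a rejection string."""
    mature_len = len(locus.sequence)
    lo, hi = criteria.mature_length_range
    if not lo <= mature_len <= hi:
        return "mature_length"
    fold = window_fold if window_fold is not None else fold_mfe(locus.window_sequence)
    m_start = locus.mature_offset
    m_end = m_start + mature_len  # half-open, window coords
    # stem-loop harbouring the mature; when random flanking sequence extends
    # the stem past the plausible precursor size, walk back down the chain to
    # the widest enclosing pair within the cap that still covers the mature
    plo, phi = criteria.precursor_length_range
    span = None
    for chain in _stem_chains(fold.pairs, criteria.max_stem_gap):
        covering = [p for p in chain if p[0] <= m_start and m_end - 1 <= p[1]]
        if not covering:
            continue
        within_cap = [p for p in covering if p[1] - p[0] + 1 <= phi]
        span = within_cap[-1] if within_cap else covering[0]
        break
    if span is None:
        return "no_stem_loop"
    i0, j0 = span
    precursor = locus.window_sequence[i0 : j0 + 1]
    refold = fold_mfe(precursor)
    hairpin_tips = [
        p for p in refold.pairs
        if not any(q[0] > p[0] and q[1] < p[1] for q in refold.pairs)
    ]
    if len(hairpin_tips) != 1:
        return "not_single_stem_loop"
    ti, tj = hairpin_tips[0]
    pm_start, pm_end = m_start - i0, m_end - i0
    if pm_end - 1 <= ti:
        arm = "5p"
    elif pm_start >= tj:
        arm = "3p"
    else:
        return "mature_spans_loop"
    paired = {i for p in refold.pairs for i in p}
    n_paired = sum(1 for k in range(pm_start, pm_end) if k in paired)
    if n_paired < criteria.min_paired_mature_bases:
        return "mature_underpaired"
    if refold.mfe > criteria.max_mfe:
        return "mfe_above_threshold"
    plen = len(precursor)
    if not plo <= plen <= phi:
        return "precursor_length"
    # precursor window coords -> genomic
    if locus.strand == "+":
        g_start = locus.window_start + i0
    else:
        g_start = locus.window_end - (j0 + 1)
    g_end = g_start + plen
    return HairpinCall(
        name="",
        mature_sequence=locus.sequence,
        mature_length=mature_len,
        chrom=locus.chrom,
        precursor_start=g_start,
        precursor_end=g_end,
        strand=locus.strand,
        arm=arm,
        precursor_length=plen,
        mfe=refold.mfe,
        structure=refold.structure,
        precursor_sequence=precursor,
        count_lib1=locus.count_lib1,
        count_lib2=locus.count_lib2,
    )


def validate_call(call: HairpinCall, genome: dict[str, str], criteria: HairpinCriteria) -> bool:
    """Independent re-check: refold the reported precursor from the genome
    and re-test every criterion on the emitted call."""
    seq = genome[call.chrom][call.precursor_start : call.precursor_end]
    if call.strand == "-":
        seq = reverse_complement(seq)
    if seq != call.precursor_sequence:
        return False
    fold = fold_mfe(seq)
    lo, hi = criteria.mature_length_range
    plo, phi = criteria.precursor_length_range
    if not (lo <= call.mature_length <= hi and plo <= call.precursor_length <= phi):
        return False
    if fold.mfe > criteria.max_mfe or abs(fold.mfe - call.mfe) > 1e-6:
        return False
    m = seq.find(call.mature_sequence)
    if m < 0:
        return False
    tips = [
        p for p in fold.pairs
        if not any(q[0] > p[0] and q[1] < p[1] for q in fold.pairs)
    ]
    if len(tips) != 1:
        return False
    ti, tj = tips[0]
    if not (m + call.mature_length - 1 <= ti or m >= tj):
        return False
    paired = {i for p in fold.pairs for i in p}
    n_paired = sum(1 for k in range(m, m + call.mature_length) if k in paired)
    return n_paired >= criteria.min_paired_mature_bases


def call_novel(
    calls: list[HairpinCall],
    mapped_total_lib1: int,
    mapped_total_lib2: int,
    min_relative_count: float = 10.0,
) -> pd.DataFrame:
    """Deduplicate by precursor interval, normalise counts (per million mapped
    reads), partition by expressing library and flag validation eligibility."""
    if mapped_total_lib1 <= 0 or mapped_total_lib2 <= 0:
        raise ValueError("mapped totals must be positive")
    best: dict[tuple, HairpinCall] = {}
    for call in calls:
        key = (call.chrom, call.precursor_start, call.precursor_end)
        prev = best.get(key)
        if prev is None or (call.mfe, call.strand) < (prev.mfe, prev.strand):
            best[key] = call
    rows = []
    ordered = sorted(best.values(), key=lambda c: (c.chrom, c.precursor_start))
    for n, call in enumerate(ordered, start=1):
        call.name = f"novel-miR-{n:02d}"
        call.rel_lib1 = 1e6 * call.count_lib1 / mapped_total_lib1
        call.rel_lib2 = 1e6 * call.count_lib2 / mapped_total_lib2
        call.eligible = max(call.rel_lib1, call.rel_lib2) > min_relative_count
        in1, in2 = call.count_lib1 > 0, call.count_lib2 > 0
        membership = "shared" if in1 and in2 else ("lib1" if in1 else "lib2")
        rows.append(
            {
                "name": call.name,
                "mature_sequence": call.mature_sequence,
                "length": call.mature_length,
                "location": call.location,
                "arm": call.arm,
                "precursor_length": call.precursor_length,
                "mfe": call.mfe,
                "rel_lib1": call.rel_lib1,
                "rel_lib2": call.rel_lib2,
                "membership": membership,
                "eligible": call.eligible,
                "chrom": call.chrom,
                "precursor_start": call.precursor_start,
                "precursor_end": call.precursor_end,
                "strand": call.strand,
                "structure": call.structure,
            }
        )
    return pd.DataFrame(rows)


def discover_novel(
    classified,
    genome: dict[str, str],
    mapped_total_lib1: int,
    mapped_total_lib2: int,
    criteria: HairpinCriteria = HairpinCriteria(),
    flank: int = DEFAULT_FLANK,
    min_relative_count: float = 10.0,
) -> pd.DataFrame:
    """Full novel-miRNA stage: unclassified tags -> windows -> hairpin calls."""
    calls: list[HairpinCall] = []
    for tag in classified:
        if tag.category != "unclassified":
            continue
        if tag.count_lib1 + tag.count_lib2 < criteria.min_total_reads:
            continue
        for placement in tag.placements:
            locus = extract_flanks(
                tag.sequence, tag.count_lib1, tag.count_lib2, placement, genome, flank
            )
            result = assess_hairpin(locus, criteria)
            if isinstance(result, HairpinCall):
                calls.append(result)
    return call_novel(calls, mapped_total_lib1, mapped_total_lib2, min_relative_count)
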