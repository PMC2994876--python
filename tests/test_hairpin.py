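"""Flank extraction, hairpin criteria and novel-candidate calling."""

import numpy as np
import pytest

from srnakit.hairpin import (
    CandidateLocus, HairpinCall, HairpinCriteria, assess_hairpin, call_novel,
    extract_flanks, validate_call,
)
from srnakit.mapping import Alignment, GenomeIndex, map_tag, reverse_complement
from srnakit.simulate import SimulationConfig, generate_reference


def test_window_arithmetic_and_clipping():
    genome = {"chr1": "A" * 10_000}
    mid = extract_flanks("C" * 22, 1, 1, Alignment("chr1", 500, "+", 0), genome)
    assert (mid.window_start, mid.window_end) == (400, 622)
    assert len(mid.window_sequence) == 222
    assert mid.mature_offset == 100
    edge = extract_flanks("C" * 22, 1, 1, Alignment("chr1", 30, "+", 0), genome)
    assert (edge.window_start, edge.window_end) == (0, 152)
    assert edge.mature_offset == 30


def test_minus_strand_window_is_reverse_complement():
    rng = np.random.default_rng(0)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 1000))}
    tag = reverse_complement(genome["chr1"][500:522])
    locus = extract_flanks(tag, 1, 1, Alignment("chr1", 500, "-", 0), genome)
    assert locus.window_sequence == reverse_complement(genome["chr1"][400:622])
    start = locus.mature_offset
    assert locus.window_sequence[start : start + 22] == tag


def test_placement_outside_genome_rejected():
    with pytest.raises(ValueError, match="outside genome"):
        extract_flanks("C" * 22, 1, 1, Alignment("chr1", 95, "+", 0), {"chr1": "A" * 100})


def _planted_candidates(seed=3):
    bundle = generate_reference(SimulationConfig(seed=seed, n_reads=1000))
    index = GenomeIndex(bundle.genome)
    out = []
    for locus in bundle.novel_loci:
        for placement in map_tag(locus.mature_sequence, index):
            out.append(
                (
                    locus,
                    extract_flanks(
                        locus.mature_sequence, 12, 8, placement, bundle.genome
                    ),
                )
            )
    return bundle, out


def test_planted_hairpins_accepted_with_correct_arm():
    bundle, candidates = _planted_candidates()
    accepted = {}
    for locus, cand in candidates:
        result = assess_hairpin(cand)
        if isinstance(result, HairpinCall):
            accepted.setdefault(locus.name, []).append((cand.strand, result))
    assert set(accepted) == {l.name for l in bundle.novel_loci}
    for locus in bundle.novel_loci:
        arms = {r.arm for s, r in accepted[locus.name] if s == locus.strand}
        assert arms == {"5p" if locus.arm == "5p" else "3p"}


def test_emitted_calls_satisfy_every_criterion_by_independent_validation():
    bundle, candidates = _planted_candidates()
    criteria = HairpinCriteria()
    for _, cand in candidates:
        result = assess_hairpin(cand, criteria)
        if isinstance(result, HairpinCall):
            assert validate_call(result, bundle.genome, criteria)
            lo, hi = criteria.precursor_length_range
            assert lo <= result.precursor_length <= hi
            assert result.mfe <= criteria.max_mfe


def test_mature_spanning_the_terminal_loop_rejected():
    # perfect stem with the "mature" centred on the loop
    arm = "GCGCGCGCGCAUAUGCGCGCGCAUGCGCAU".replace("U", "T")
    hairpin = arm + "GAGAGAGAGAGA" + reverse_complement(arm)
    genome = {"chr1": "A" * 100 + hairpin + "A" * 100}
    m_start = 100 + len(arm) - 5  # 22-mer straddling the loop
    tagseq = genome["chr1"][m_start : m_start + 22]
    locus = extract_flanks(tagseq, 9, 9, Alignment("chr1", m_start, "+", 0), genome)
    assert assess_hairpin(locus) == "mature_spans_loop"


def test_weak_structure_rejected_before_mfe():
    rng = np.random.default_rng(5)
    window = "".join(rng.choice(list("ACGT"), 222))
    locus = CandidateLocus(
        window[100:122], 9, 9, "chr1", "+", 100, 122, 0, 222, window, 100
    )
    result = assess_hairpin(locus)
    assert isinstance(result, str)


def test_mature_length_gate():
    locus = CandidateLocus("A" * 19, 9, 9, "chr1", "+", 0, 19, 0, 219, "A" * 219, 100)
    assert assess_hairpin(locus) == "mature_length"


def _call(name, chrom, start, end, c1, c2, mfe=-30.0):
    return HairpinCall(
        name=name, mature_sequence="A" * 22, mature_length=22, chrom=chrom,
        precursor_start=start, precursor_end=end, strand="+", arm="5p",
        precursor_length=end - start, mfe=mfe, structure="", precursor_sequence="",
        count_lib1=c1, count_lib2=c2,
    )


def test_call_novel_partitions_and_eligibility():
    calls = [
        _call("a", "chr1", 100, 180, 50, 60),    # shared
        _call("b", "chr1", 400, 480, 0, 12),     # lib2-specific, eligible
        _call("c", "chr2", 100, 170, 3, 0),      # lib1-specific, low expression
        _call("a2", "chr1", 100, 180, 50, 60, mfe=-20.0),  # duplicate interval
    ]
    table = call_novel(calls, mapped_total_lib1=1_000_000, mapped_total_lib2=1_000_000)
    assert len(table) == 3
    by_membership = dict(zip(table["membership"], table["name"]))
    assert set(by_membership) == {"shared", "lib1", "lib2"}
    lib2_row = table[table["membership"] == "lib2"].iloc[0]
    assert lib2_row["rel_lib2"] == pytest.approx(12.0)
    assert bool(lib2_row["eligible"])
    lib1_row = table[table["membership"] == "lib1"].iloc[0]
    assert not bool(lib1_row["eligible"])
    # duplicate interval deduplicated to the more stable fold
    shared = table[table["membership"] == "shared"].iloc[0]
    assert shared["mfe"] == pytest.approx(-30.0)


def test_call_novel_requires_positive_totals():
    with pytest.raises(ValueError):
        call_novel([], 0, 10)
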