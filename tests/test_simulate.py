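"""Synthetic-data generator: determinism, construction invariants, sampling."""

import math

import numpy as np
import pandas as pd
import pytest

from srnakit.mapping import reverse_complement
from srnakit.preprocess import clean_library, collapse_tags
from srnakit.io import FastqRead
from srnakit.simulate import (
    ConfigError, SimulationConfig, SizingError, generate_reference,
    simulate_reads,
)


def small_config(**overrides):
    defaults = dict(seed=1, n_reads=2000, n_mirnas=40, n_de_up=5, n_de_down=5,
                    n_fragment_species=50, n_junk_species=30)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def test_identical_seed_gives_byte_identical_libraries():
    cfg = small_config()
    b1 = generate_reference(cfg)
    b2 = generate_reference(cfg)
    assert b1.genome == b2.genome
    assert b1.fold_changes == b2.fold_changes
    r1a, r2a, truth_a = simulate_reads(b1, cfg)
    r1b, r2b, truth_b = simulate_reads(b2, cfg)
    assert r1a == r1b and r2a == r2b
    pd.testing.assert_frame_equal(truth_a.species, truth_b.species)


def test_catalog_matures_occur_verbatim_at_their_placements():
    cfg = small_config(n_mirnas=10, n_de_up=2, n_de_down=2)
    bundle = generate_reference(cfg)
    assert len(bundle.mirna_catalog) == 10
    for rec in bundle.mirna_catalog:
        genomic = bundle.genome[rec.chrom][rec.mature_start : rec.mature_end]
        expected = genomic if rec.strand == "+" else reverse_complement(genomic)
        assert rec.mature_sequence == expected
        assert rec.precursor_start <= rec.mature_start < rec.mature_end <= rec.precursor_end


def test_annotations_lie_within_chromosome_bounds():
    bundle = generate_reference(small_config())
    for iv in bundle.annotations:
        assert 0 <= iv.start < iv.end <= len(bundle.genome[iv.chrom])


def test_planted_hairpin_arms_are_near_reverse_complements():
    """Each planted locus folds back on itself: >= 16 complementary positions
    between the two arms, checked by direct string comparison."""
    cfg = small_config(novel_loci={"shared": 1, "lib1": 1, "lib2": 1})
    bundle = generate_reference(cfg)
    assert len(bundle.novel_loci) == 3
    catalog_names = {rec.name for rec in bundle.mirna_catalog}
    for locus in bundle.novel_loci:
        assert locus.name not in catalog_names
        hairpin = bundle.genome[locus.chrom][locus.start : locus.end]
        # arms = equal halves excluding the middle loop region
        arm = (locus.end - locus.start - 8) // 2
        arm1, arm2 = hairpin[:arm], hairpin[-arm:]
        matches = sum(
            1 for a, b in zip(arm1, reverse_complement(arm2)) if a == b
        )
        assert matches >= 16, locus.name
        # mature occurs verbatim inside the locus
        seq = bundle.genome[locus.chrom][locus.mature_start : locus.mature_end]
        if locus.strand == "-":
            seq = reverse_complement(seq)
        assert seq == locus.mature_sequence


def test_degenerate_mixture_yields_only_that_mature_plus_adapter():
    cfg = small_config(
        n_mirnas=1, n_de_up=0, n_de_down=0, n_reads=100, error_rate=0.0,
        low_quality_fraction=0.0,
        novel_loci={"shared": 0, "lib1": 0, "lib2": 0},
        mixture_lib1={"miRNA": 1.0},
        mixture_lib2={"miRNA": 1.0},
    )
    bundle = generate_reference(cfg)
    mature = bundle.mirna_catalog[0].mature_sequence
    reads1, reads2, _ = simulate_reads(bundle, cfg)
    assert len(reads1) == len(reads2) == 100
    for _, seq, _ in reads1:
        assert seq.startswith(mature)
        assert seq[len(mature) :].startswith(cfg.adapter3[: 40 - len(mature)])


def test_zero_mirna_mixture_with_planted_fold_changes_rejected():
    cfg = small_config(
        mixture_lib1={"junk": 1.0}, mixture_lib2={"junk": 1.0}
    )
    bundle = generate_reference(cfg)
    with pytest.raises(ConfigError, match="zero miRNA mixture"):
        simulate_reads(bundle, cfg)


def test_mixture_must_sum_to_one():
    with pytest.raises(ConfigError, match="sum to 1"):
        small_config(mixture_lib1={"miRNA": 0.5, "junk": 0.2})


def test_chromosomes_too_short_raise_sizing_error():
    with pytest.raises(SizingError):
        generate_reference(small_config(chrom_lengths={"chr1": 250}))
    with pytest.raises(SizingError):
        # long enough for flanks but not for 40 precursors
        generate_reference(small_config(chrom_lengths={"chr1": 400}))


def test_read_conservation_and_planted_ratio_recovery():
    """A 4x planted miRNA shows a count ratio within 3 binomial SDs.

    With many null miRNAs the within-category composition shift from one
    planted fold is small, so the normalised truth ratio sits near 4.
    """
    cfg = small_config(
        n_reads=30_000, n_mirnas=150, n_de_up=0, n_de_down=0,
        fold_changes={"mir-007": 4.0}, error_rate=0.0,
        low_quality_fraction=0.0,
    )
    bundle = generate_reference(cfg)
    reads1, reads2, truth = simulate_reads(bundle, cfg)
    assert len(reads1) == len(reads2) == cfg.n_reads
    mature = {r.name: r.mature_sequence for r in bundle.mirna_catalog}["mir-007"]
    x = sum(1 for _, seq, _ in reads1 if seq.startswith(mature))
    y = sum(1 for _, seq, _ in reads2 if seq.startswith(mature))
    row = truth.mirna.set_index("name").loc["mir-007"]
    assert row["de_status"] == "up"
    assert row["true_ratio"] == pytest.approx(4.0, rel=0.10)
    expected_y = row["expected_count_lib2"]
    assert abs(y - expected_y) <= 3 * math.sqrt(expected_y)
    # empirical count ratio within 3 (combined) binomial SDs of the planted 4x
    expected_ratio = row["expected_count_lib2"] / row["expected_count_lib1"]
    ratio_sd = expected_ratio * math.sqrt(1.0 / max(x, 1) + 1.0 / max(y, 1))
    assert abs(y / x - expected_ratio) <= 3 * ratio_sd


def test_truth_species_expected_counts_sum_to_depth():
    cfg = small_config()
    bundle = generate_reference(cfg)
    _, _, truth = simulate_reads(bundle, cfg)
    assert truth.species["expected_count_lib1"].sum() == pytest.approx(cfg.n_reads)
    assert truth.species["expected_count_lib2"].sum() == pytest.approx(cfg.n_reads)


def test_shared_tag_fraction_matches_planted_overlap():
    """Observed tag sharing between libraries tracks a Poisson-detection
    prediction computed from the TruthTable expectations."""
    cfg = small_config(n_reads=40_000, error_rate=0.0, low_quality_fraction=0.0)
    bundle = generate_reference(cfg)
    reads1, reads2, truth = simulate_reads(bundle, cfg)

    def inserts(triples):
        reads = [FastqRead(n, s, tuple([40] * len(s))) for n, s, q in triples]
        out, _ = clean_library(reads, cfg.adapter3)
        return out

    tags = collapse_tags(inserts(reads1), inserts(reads2))
    observed_shared = (
        ((tags["count_lib1"] > 0) & (tags["count_lib2"] > 0)).sum() / len(tags)
    )
    lam1 = truth.species["expected_count_lib1"].to_numpy()
    lam2 = truth.species["expected_count_lib2"].to_numpy()
    # only 18-30 nt species survive the retention rule
    lengths = truth.species["sequence"].str.len().to_numpy()
    keep = (lengths >= 18) & (lengths <= 30)
    p1, p2 = 1 - np.exp(-lam1[keep]), 1 - np.exp(-lam2[keep])
    predicted_shared = (p1 * p2).sum() / (1 - (1 - p1) * (1 - p2)).sum()
    assert observed_shared == pytest.approx(predicted_shared, abs=0.05)
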