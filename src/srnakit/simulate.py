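"""Synthetic two-library small-RNA experiment with planted ground truth.

``generate_reference`` builds a mini-genome carrying miRNA precursors with
catalogued matures, ncRNA/repeat/mRNA degradation-source intervals and
planted novel hairpin loci (designed stem-loops absent from the catalog).
``simulate_reads`` then emits two FASTQ libraries whose composition, insert
lengths, planted fold changes and planted novel expression are recorded in a
TruthTable for parameter-recovery testing.

Defaults emulate an androgen-dependent vs androgen-independent prostate
cancer library pair: ~22-nt modal inserts, a miRNA-dominated mapped fraction
(65.2% / 62.3% of mapped reads), ~94% of retained reads mappable, 40 up- and
40 down-regulated miRNAs planted at 4-25x with mirrored fold lists so the
within-miRNA composition stays balanced across libraries, and ten novel
hairpin loci split into shared / library-1-only / library-2-only classes.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationInterval, MatureRecord
from .io import write_fasta, write_fastq
from .mapping import reverse_complement

CATEGORY_ORDER = ("miRNA", "ncRNA", "repeat", "mRNA", "novel", "junk")

# 3' adapter in DNA form (sequencers emit DNA basecalls); the 5' adapter is
# assumed removed by the instrument and recorded for provenance only.
ADAPTER3_DNA = "TCGTATGCCGTCTTCTGCTTG"
ADAPTER5_DNA = "GTTCAGAGTTCTACAGTCCGACGATC"

_MATURE_LENGTH_WEIGHTS = {20: 0.10, 21: 0.20, 22: 0.40, 23: 0.20, 24: 0.10}


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


class SizingError(ValueError):
    """Chromosomes too short for the requested features."""


def _default_mixture_lib1() -> dict[str, float]:
    return {
        "miRNA": 0.61424, "ncRNA": 0.17, "repeat": 0.09,
        "mRNA": 0.05456, "novel": 0.013, "junk": 0.0582,
    }


def _default_mixture_lib2() -> dict[str, float]:
    return {
        "miRNA": 0.58360, "ncRNA": 0.18, "repeat": 0.10,
        "mRNA": 0.06, "novel": 0.0127, "junk": 0.0637,
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; the seed fixes all randomness."""

    n_reads: int = 100_000
    read_length: int = 40
    modal_insert_length: int = 22
    length_scale: float = 1.5  # Laplace decay of insert length around the mode
    mixture_lib1: dict[str, float] = field(default_factory=_default_mixture_lib1)
    mixture_lib2: dict[str, float] = field(default_factory=_default_mixture_lib2)
    n_mirnas: int = 200
    n_de_up: int = 40
    n_de_down: int = 40
    de_fold_range: tuple[float, float] = (4.0, 25.0)
    fold_changes: dict[str, float] | None = None  # explicit name -> lib2/lib1 ratio
    novel_loci: dict[str, int] = field(
        default_factory=lambda: {"shared": 4, "lib1": 3, "lib2": 3}
    )
    n_fragment_species: int = 300
    n_junk_species: int = 200
    adapter3: str = ADAPTER3_DNA
    adapter5: str = ADAPTER5_DNA
    error_rate: float = 0.001
    low_quality_fraction: float = 0.005
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 45_000, "chr2": 25_000}
    )
    seed: int = 0

    def __post_init__(self):
        for label, mix in (("lib1", self.mixture_lib1), ("lib2", self.mixture_lib2)):
            unknown = set(mix) - set(CATEGORY_ORDER)
            if unknown:
                raise ConfigError(f"unknown mixture categories in {label}: {unknown}")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"negative mixture proportion in {label}")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{label} mixture proportions must sum to 1")
        if self.fold_changes is not None and any(
            r <= 0 for r in self.fold_changes.values()
        ):
            raise ConfigError("planted fold-change ratios must be positive")
        if self.n_de_up + self.n_de_down > self.n_mirnas:
            raise ConfigError("more planted DE miRNAs than miRNAs")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error rate must be in [0, 1)")
        if self.n_reads <= 0:
            raise ConfigError("n_reads must be positive")

    def mixture(self, library: int) -> dict[str, float]:
        return self.mixture_lib1 if library == 1 else self.mixture_lib2

    def to_file(self, path: str | Path) -> None:
        """Plain-text key=value dump (dict values as k:v comma lists)."""
        with open(path, "w") as handle:
            for key, value in self.__dict__.items():
                if isinstance(value, dict):
                    value = ",".join(f"{k}:{v}" for k, v in value.items())
                elif isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                handle.write(f"{key} = {value}\n")


@dataclass(frozen=True)
class NovelLocus:
    """A planted hairpin: designed stem-loop absent from the miRNA catalog."""

    name: str
    chrom: str
    start: int  # precursor, 0-based half-open
    end: int
    strand: str
    mature_sequence: str
    mature_start: int
    mature_end: int
    arm: str  # 5p / 3p
    membership: str  # shared / lib1 / lib2


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    annotations: list[AnnotationInterval]
    mirna_catalog: list[MatureRecord]
    novel_loci: list[NovelLocus]
    fold_changes: dict[str, float]

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                    "name": iv.name, "score": 0, "strand": iv.strand,
                    "category": iv.category,
                }
                for iv in self.annotations
            ]
        )


@dataclass
class TruthTable:
    """Planted ground truth: per-entity expected counts and labels."""

    mirna: pd.DataFrame   # name, expected per-library counts, ratio, de_status
    novel: pd.DataFrame   # locus coordinates, membership, expected counts
    species: pd.DataFrame  # every simulated insert species with expectations

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mirna.to_csv(directory / "truth_mirna.tsv", sep="\t", index=False)
        self.novel.to_csv(directory / "truth_novel.tsv", sep="\t", index=False)
        self.species.to_csv(directory / "truth_species.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "TruthTable":
        directory = Path(directory)
        return cls(
            pd.read_csv(directory / "truth_mirna.tsv", sep="\t"),
            pd.read_csv(directory / "truth_novel.tsv", sep="\t"),
            pd.read_csv(directory / "truth_species.tsv", sep="\t"),
        )


def _length_pmf(lo: int, hi: int, mode: int, scale: float) -> dict[int, float]:
    weights = {L: math.exp(-abs(L - mode) / scale) for L in range(lo, hi + 1)}
    total = sum(weights.values())
    return {L: w / total for L, w in weights.items()}


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), length)])


class _Allocator:
    """Sequential feature placement with random intergenic gaps."""

    def __init__(self, rng, chrom_lengths, margin=150, gap_range=(30, 80)):
        self.rng = rng
        self.lengths = dict(chrom_lengths)
        self.cursors = {c: margin for c in chrom_lengths}
        self.margin = margin
        self.gap_range = gap_range

    def place(self, size: int) -> tuple[str, int]:
        order = sorted(
            self.lengths, key=lambda c: self.cursors[c] / self.lengths[c]
        )
        for chrom in order:
            gap = int(self.rng.integers(*self.gap_range))
            start = self.cursors[chrom] + gap
            if start + size + self.margin <= self.lengths[chrom]:
                self.cursors[chrom] = start + size
                return chrom, start
        raise SizingError(
            f"chromosomes too short: cannot place a {size}-nt feature"
        )


def _plant_fold_changes(rng, names: list[str], config) -> dict[str, float]:
    """Mirrored up/down fold lists (balanced composition across libraries)."""
    if config.fold_changes is not None:
        return dict(config.fold_changes)
    n_up, n_down = config.n_de_up, config.n_de_down
    chosen = rng.choice(len(names), size=n_up + n_down, replace=False)
    lo, hi = config.de_fold_range
    folds = np.exp(rng.uniform(math.log(lo), math.log(hi), size=max(n_up, n_down)))
    out: dict[str, float] = {}
    for i, idx in enumerate(chosen[:n_up]):
        out[names[idx]] = float(folds[i])
    for i, idx in enumerate(chosen[n_up:]):
        out[names[idx]] = float(1.0 / folds[i])
    return out


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Deterministically build genome, annotations, catalog and novel loci."""
    rng = np.random.default_rng(config.seed)
    longest_precursor = 100
    for chrom, length in config.chrom_lengths.items():
        if length < 2 * 100 + longest_precursor:
            raise SizingError(f"{chrom} shorter than 2*flank + longest precursor")
    genome = {
        chrom: list(_random_seq(rng, length))
        for chrom, length in config.chrom_lengths.items()
    }
    alloc = _Allocator(rng, config.chrom_lengths)
    annotations: list[AnnotationInterval] = []
    catalog: list[MatureRecord] = []

    mature_lengths = list(_MATURE_LENGTH_WEIGHTS)
    mature_probs = np.array(list(_MATURE_LENGTH_WEIGHTS.values()))
    for i in range(config.n_mirnas):
        name = f"mir-{i + 1:03d}"
        prec_len = int(rng.integers(70, 91))
        mature_len = int(rng.choice(mature_lengths, p=mature_probs))
        strand = "+" if rng.random() < 0.5 else "-"
        arm = "5p" if rng.random() < 0.5 else "3p"
        chrom, start = alloc.place(prec_len)
        end = start + prec_len
        off = int(rng.integers(1, 6))
        left_arm = arm == "5p" if strand == "+" else arm == "3p"
        if left_arm:
            m_start = start + off
        else:
            m_start = end - off - mature_len
        m_end = m_start + mature_len
        seq = "".join(genome[chrom][m_start:m_end])
        mature_seq = seq if strand == "+" else reverse_complement(seq)
        annotations.append(
            AnnotationInterval(chrom, start, end, strand, "miRNA", name)
        )
        catalog.append(
            MatureRecord(name, mature_seq, chrom, start, end, m_start, m_end, strand, arm)
        )

    for category, count, size_range in (
        ("ncRNA", 30, (100, 300)),
        ("repeat", 20, (200, 500)),
        ("mRNA", 15, (300, 800)),
    ):
        for i in range(count):
            size = int(rng.integers(*size_range))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = alloc.place(size)
            annotations.append(
                AnnotationInterval(
                    chrom, start, start + size, strand, category, f"{category}-{i + 1:03d}"
                )
            )

    novel: list[NovelLocus] = []
    serial = 0
    for membership in ("shared", "lib1", "lib2"):
        for _ in range(int(config.novel_loci.get(membership, 0))):
            serial += 1
            locus = _plant_hairpin(rng, alloc, genome, f"novel-{serial:02d}", membership)
            novel.append(locus)

    genome_str = {chrom: "".join(bases) for chrom, bases in genome.items()}
    names = [rec.name for rec in catalog]
    fold_changes = _plant_fold_changes(rng, names, config)
    return ReferenceBundle(genome_str, annotations, catalog, novel, fold_changes)


def _plant_hairpin(rng, alloc, genome, name, membership) -> NovelLocus:
    """Write a designed stem-loop into the genome.

    Arms are reverse complements except for three substitutions placed
    opposite the mature span, so the mature tag maps uniquely (>2 DNA
    mismatches from the far arm).  Substitution sites are chosen where the
    mature base is G or T so the mutated partner still forms a G-U wobble
    pair as RNA: the stem keeps folding as one helix while the sequences
    diverge.  The loop is drawn from {A, G} (purine-only), which cannot pair
    with itself on either strand orientation.
    The mature lies on the genomic-left arm; the random strand choice makes
    it the 5' arm on '+' loci and the 3' arm on '-' loci in transcript
    orientation.
    """
    loop_len = int(rng.integers(8, 15))
    mature_len = int(rng.integers(20, 25))
    strand = "+" if rng.random() < 0.5 else "-"
    # the mature sits >= 3 bp interior to its arm, so terminal helix fraying
    # against flanking sequence cannot strip mature bases off the stem
    m_off = int(rng.integers(3, 6))
    arm_len = m_off + mature_len + int(rng.integers(3, 6))
    arm1 = _random_seq(rng, arm_len)
    loop = _random_seq(rng, loop_len, "AG")
    # wobble pairing is not strand-symmetric: pick substitutions that read as
    # G-U in TRANSCRIPT orientation (the orientation that gets folded)
    if strand == "+":
        eligible_bases, wobble = "GT", {"G": "T", "T": "G"}
    else:
        eligible_bases, wobble = "CA", {"C": "A", "A": "C"}
    interior = range(m_off + 2, m_off + mature_len - 2)
    eligible = [t for t in interior if arm1[t] in eligible_bases]
    while len(eligible) < 3:  # vanishingly rare with >= 20-nt matures
        arm1 = _random_seq(rng, arm_len)
        eligible = [t for t in interior if arm1[t] in eligible_bases]
    chosen = {eligible[0], eligible[len(eligible) // 2], eligible[-1]}
    while len(chosen) < 3:
        chosen.add(eligible[int(rng.integers(len(eligible)))])
    arm2 = list(reverse_complement(arm1))
    for t in sorted(chosen):
        arm2[arm_len - 1 - t] = wobble[arm1[t]]
    hairpin = arm1 + loop + "".join(arm2)
    chrom, start = alloc.place(len(hairpin))
    end = start + len(hairpin)
    genome[chrom][start:end] = list(hairpin)
    g_m_start = start + m_off
    g_m_end = g_m_start + mature_len
    seq = hairpin[m_off : m_off + mature_len]
    mature_seq = seq if strand == "+" else reverse_complement(seq)
    arm = "5p" if strand == "+" else "3p"
    return NovelLocus(
        name, chrom, start, end, strand, mature_seq, g_m_start, g_m_end, arm, membership
    )


def _build_species(rng, bundle: ReferenceBundle, config: SimulationConfig) -> pd.DataFrame:
    """One row per insert species: sequence, category, per-library weights."""
    frag_pmf = _length_pmf(18, 30, config.modal_insert_length, config.length_scale)
    junk_pmf = _length_pmf(15, 30, config.modal_insert_length, config.length_scale)
    rows = []
    for rec in bundle.mirna_catalog:
        ratio = bundle.fold_changes.get(rec.name, 1.0)
        if rec.name in bundle.fold_changes:
            # planted DE: unit base abundance, the fold scales the high side
            w1 = max(1.0, 1.0 / ratio)
            w2 = max(1.0, ratio)
        else:
            w1 = w2 = float(rng.lognormal(0.0, 0.8))
        rows.append((rec.name, "miRNA", rec.mature_sequence, w1, w2))

    by_category: dict[str, list[AnnotationInterval]] = {}
    for iv in bundle.annotations:
        if iv.category != "miRNA":
            by_category.setdefault(iv.category, []).append(iv)
    lengths = np.array(list(frag_pmf), dtype=int)
    probs = np.array(list(frag_pmf.values()))
    for category in ("ncRNA", "repeat", "mRNA"):
        intervals = by_category.get(category, [])
        seen = set()
        for i in range(config.n_fragment_species):
            iv = intervals[int(rng.integers(len(intervals)))]
            L = int(rng.choice(lengths, p=probs))
            L = min(L, iv.end - iv.start)
            start = iv.start + int(rng.integers(0, iv.end - iv.start - L + 1))
            seq = bundle.genome[iv.chrom][start : start + L]
            if iv.strand == "-":
                seq = reverse_complement(seq)
            if seq in seen:
                continue
            seen.add(seq)
            w = float(rng.lognormal(0.0, 0.8))
            rows.append((f"{category}-frag-{i + 1:04d}", category, seq, w, w))

    for locus in bundle.novel_loci:
        w = float(rng.lognormal(0.0, 0.3))
        w1 = w if locus.membership in ("shared", "lib1") else 0.0
        w2 = w if locus.membership in ("shared", "lib2") else 0.0
        rows.append((locus.name, "novel", locus.mature_sequence, w1, w2))

    junk_lengths = np.array(list(junk_pmf), dtype=int)
    junk_probs = np.array(list(junk_pmf.values()))
    for i in range(config.n_junk_species):
        L = int(rng.choice(junk_lengths, p=junk_probs))
        seq = _random_seq(rng, L)
        w = float(rng.lognormal(0.0, 0.8))
        rows.append((f"junk-{i + 1:04d}", "junk", seq, w, w))

    return pd.DataFrame(rows, columns=["name", "category", "sequence", "w1", "w2"])


def _species_probabilities(species: pd.DataFrame, mixture: dict[str, float], wcol: str) -> np.ndarray:
    """Per-species sampling probabilities hitting the RETAINED composition.

    The target mixture describes the composition of reads surviving the
    18-30 nt retention rule, so each category's raw sampling mass is divided
    by its retention factor (only junk carries sub-18-nt inserts).
    """
    probs = np.zeros(len(species))
    lengths = species["sequence"].str.len()
    for category, target in mixture.items():
        sel = (species["category"] == category).to_numpy()
        if target <= 0 or not sel.any():
            continue
        w = species.loc[sel, wcol].to_numpy(dtype=float)
        if w.sum() <= 0:
            continue
        retained = np.where((lengths[sel] >= 18) & (lengths[sel] <= 30), w, 0.0)
        retention = retained.sum() / w.sum() if w.sum() else 1.0
        if retention <= 0:
            retention = 1.0
        probs[sel] = target / retention * w / w.sum()
    return probs / probs.sum()


_CODE = {b: i for i, b in enumerate("ACGT")}
_DECODE = np.array(list("ACGT"))


def _emit_library(rng, species, probs, config, lib_label):
    """Sample reads for one library; returns FASTQ triples + realised counts."""
    counts = rng.multinomial(config.n_reads, probs)
    L = config.read_length
    n_total = int(counts.sum())
    template = np.zeros((len(species), L), dtype=np.uint8)
    for idx, seq in enumerate(species["sequence"]):
        full = (seq + config.adapter3 + "A" * L)[:L]
        template[idx] = [_CODE[b] for b in full]
    read_species = np.repeat(np.arange(len(species)), counts)
    reads = template[read_species].copy()
    if config.error_rate > 0 and n_total:
        mask = rng.random((n_total, L)) < config.error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        reads[mask] = (reads[mask] + shifts) % 4
    low_q = rng.random(n_total) < config.low_quality_fraction
    good_qual = "I" * L
    bad_qual = "#" * L
    triples = []
    for i in range(n_total):
        seq = "".join(_DECODE[reads[i]])
        name = f"{lib_label}_{i + 1:07d}"
        triples.append((name, seq, bad_qual if low_q[i] else good_qual))
    return triples, counts


def simulate_reads(
    bundle: ReferenceBundle, config: SimulationConfig
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], TruthTable]:
    """Sample both libraries and the TruthTable recording expectations.

    Reads are (identifier, sequence, quality) FASTQ triples; exactly
    config.n_reads per library are emitted.
    """
    if bundle.fold_changes and config.mixture_lib1.get("miRNA", 0.0) <= 0:
        raise ConfigError("planted miRNA fold changes with zero miRNA mixture")
    if bundle.fold_changes and config.mixture_lib2.get("miRNA", 0.0) <= 0:
        raise ConfigError("planted miRNA fold changes with zero miRNA mixture")
    rng = np.random.default_rng(config.seed + 1)
    species = _build_species(rng, bundle, config)
    p1 = _species_probabilities(species, config.mixture_lib1, "w1")
    p2 = _species_probabilities(species, config.mixture_lib2, "w2")
    reads1, _ = _emit_library(rng, species, p1, config, "lib1")
    reads2, _ = _emit_library(rng, species, p2, config, "lib2")

    species = species.assign(
        expected_count_lib1=config.n_reads * p1,
        expected_count_lib2=config.n_reads * p2,
    )
    mirna = species[species["category"] == "miRNA"].copy()
    share1 = mirna["expected_count_lib1"] / mirna["expected_count_lib1"].sum()
    share2 = mirna["expected_count_lib2"] / mirna["expected_count_lib2"].sum()
    ratio = share2 / share1
    mirna = mirna.assign(true_ratio=ratio)
    planted = mirna["name"].map(lambda n: n in bundle.fold_changes)
    mirna = mirna.assign(
        de_status=np.select(
            [planted & (ratio >= 2.0), planted & (ratio <= 0.5)],
            ["up", "down"],
            default="none",
        )
    )[
        [
            "name", "expected_count_lib1", "expected_count_lib2",
            "true_ratio", "de_status",
        ]
    ]
    novel_rows = []
    for locus in bundle.novel_loci:
        row = species[species["name"] == locus.name].iloc[0]
        novel_rows.append(
            {
                "name": locus.name, "chrom": locus.chrom,
                "precursor_start": locus.start, "precursor_end": locus.end,
                "strand": locus.strand, "mature_sequence": locus.mature_sequence,
                "arm": locus.arm, "membership": locus.membership,
                "expected_count_lib1": row["expected_count_lib1"],
                "expected_count_lib2": row["expected_count_lib2"],
            }
        )
    truth = TruthTable(
        mirna=mirna.reset_index(drop=True),
        novel=pd.DataFrame(novel_rows),
        species=species[
            [
                "name", "category", "sequence",
                "expected_count_lib1", "expected_count_lib2",
            ]
        ].copy(),
    )
    return reads1, reads2, truth


def simulate_to_files(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """End-to-end simulation writing FASTA/BED/FASTQ/TSV artefacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_reference(config)
    reads1, reads2, truth = simulate_reads(bundle, config)
    paths = {
        "genome": out / "genome.fa",
        "annotations": out / "annotations.bed",
        "catalog": out / "mirna_catalog.tsv",
        "fastq_lib1": out / "lib1.fastq",
        "fastq_lib2": out / "lib2.fastq",
        "config": out / "config.txt",
    }
    write_fasta(paths["genome"], bundle.genome)
    bundle.annotation_frame().to_csv(
        paths["annotations"], sep="\t", header=False, index=False
    )
    pd.DataFrame([rec.__dict__ for rec in bundle.mirna_catalog]).to_csv(
        paths["catalog"], sep="\t", index=False
    )
    write_fastq(paths["fastq_lib1"], reads1)
    write_fastq(paths["fastq_lib2"], reads2)
    config.to_file(paths["config"])
    truth.write(out)
    return paths
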