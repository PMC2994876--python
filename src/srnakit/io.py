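"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTQ/FASTA go through Biopython; tabular reports are TSV with a header line
and are schema-checked before writing.  Annotations travel as 6-column BED
(0-based half-open, strand in column 6) plus a seventh category column.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class FastqRead:
    """One raw read: identifier, base calls and Phred qualities."""

    identifier: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.identifier!r}: sequence and quality lengths differ"
            )


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate records of a Sanger (Phred+33) FASTQ file."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record {title.split()[0]!r}")
            yield FastqRead(
                title.split()[0], seq.upper(), tuple(ord(c) - 33 for c in qual)
            )


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (identifier, sequence, quality-string) triples as FASTQ."""
    with open(path, "w") as handle:
        for ident, seq, qual in reads:
            handle.write(f"@{ident}\n{seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_tags_fasta(path: str | Path, tags: pd.DataFrame) -> None:
    """Non-redundant FASTA with count-bearing headers (>tagN_x{count})."""
    with open(path, "w") as handle:
        for n, row in enumerate(tags.itertuples(), start=1):
            total = int(row.count_lib1) + int(row.count_lib2)
            handle.write(f">tag{n}_x{total}\n{row.sequence}\n")


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "category"]


def read_bed_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed_annotations(path: str | Path, df: pd.DataFrame) -> None:
    _check_schema(df, BED_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


def _check_schema(df: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"report is missing required columns: {missing}")


def write_report(path: str | Path, df: pd.DataFrame, columns: list[str]) -> None:
    """Schema-validated TSV report writer (fixed column order, header line)."""
    _check_schema(df, columns)
    df.to_csv(path, sep="\t", index=False, columns=columns)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_pvalue(p: float) -> str:
    """Scientific-notation P-value formatting ('6.86E-57'; exact zero as '0')."""
    if p == 0:
        return "0"
    return f"{p:.2E}"


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def genomic_location(chrom: str, start0: int, end0: int, strand: str) -> str:
    """Human-facing 1-based inclusive locus string, 'chr6:28918819:28918903:+'."""
    return f"{chrom}:{start0 + 1}:{end0}:{strand}"


def precursor_length(start1: int, end1: int) -> int:
    """Length of a 1-based inclusive genomic interval."""
    if end1 < start1:
        raise ValueError("interval end before start")
    return end1 - start1 + 1
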