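"""Pipeline-wide configuration: every stage parameter in one place.

The config file format is plain ``key = value`` text; dict-valued keys use
``k:v`` comma lists and unknown keys are rejected.  CLI flags override file
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .simulate import ADAPTER3_DNA, ADAPTER5_DNA


@dataclass
class PipelineConfig:
    # preprocessing
    adapter3: str = ADAPTER3_DNA
    adapter5: str = ADAPTER5_DNA
    max_n: int = 0
    min_mean_quality: float = 20.0
    min_adapter_overlap: int = 8
    min_length: int = 18
    max_length: int = 30
    # mapping / annotation
    max_mismatch: int = 2
    annotation_priority: tuple[str, ...] = ("miRNA", "ncRNA", "repeat", "mRNA")
    min_overlap_fraction: float = 0.5
    isomir_window: int = 3
    # differential expression
    p_threshold: float = 0.001
    fc_threshold: float = 2.0
    # novel miRNA discovery
    flank: int = 100
    max_mfe: float = -18.0
    min_paired_mature_bases: int = 16
    precursor_min: int = 60
    precursor_max: int = 100
    mature_min: int = 20
    mature_max: int = 24
    min_candidate_reads: int = 5
    min_novel_relative_count: float = 10.0
    # targets / enrichment
    min_support: int = 3
    enrich_alpha: float = 0.001
    # simulation / global
    seed: int = 0
    n_reads: int = 100_000

    _RANGES = {
        "max_n": (0, 10),
        "min_mean_quality": (0.0, 45.0),
        "min_adapter_overlap": (1, 30),
        "min_length": (1, 100),
        "max_length": (1, 100),
        "max_mismatch": (0, 3),
        "min_overlap_fraction": (0.0, 1.0),
        "isomir_window": (0, 10),
        "p_threshold": (0.0, 1.0),
        "fc_threshold": (1.0, 1e6),
        "flank": (10, 1000),
        "min_support": (1, 10),
        "enrich_alpha": (0.0, 1.0),
        "n_reads": (1, 100_000_000),
    }

    def __post_init__(self):
        for key, (lo, hi) in self._RANGES.items():
            value = getattr(self, key)
            if not lo <= value <= hi:
                raise ValueError(f"config key {key}={value} outside [{lo}, {hi}]")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.precursor_min > self.precursor_max:
            raise ValueError("precursor_min > precursor_max")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls) if not f.name.startswith("_")}
        values = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"line {lineno}: expected 'key = value'")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                values[key] = _coerce(raw, known[key].type)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for f in fields(self):
                if f.name.startswith("_"):
                    continue
                value = getattr(self, f.name)
                if isinstance(value, tuple):
                    value = ",".join(map(str, value))
                handle.write(f"{f.name} = {value}\n")


def _coerce(raw: str, annotation):
    text = str(annotation)
    if "tuple" in text:
        return tuple(item.strip() for item in raw.split(","))
    if "int" in text:
        return int(raw)
    if "float" in text:
        return float(raw)
    return raw
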