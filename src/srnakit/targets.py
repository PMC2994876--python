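"""miRNA target consensus and gene-set enrichment.

Target predictions arrive as per-tool (miRNA, gene) pair sets — either read
from TSV files produced by external predictors or generated by the built-in
seed-match predictor, which lets the whole pipeline run hermetically on
synthetic 3' UTRs.  A pair is a consensus target when supported by at least
``min_support`` (default 3) distinct tools.  Enrichment of the consensus
genes in gene sets uses the upper-tail hypergeometric probability with
Benjamini-Hochberg adjustment across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mapping import reverse_complement

DEFAULT_MIN_SUPPORT = 3
DEFAULT_ENRICH_ALPHA = 0.001


@dataclass(frozen=True)
class PredictionSet:
    """One tool's predicted (miRNA, gene) pairs."""

    tool: str
    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, tool: str, pairs) -> "PredictionSet":
        return cls(tool, frozenset(pairs))


def seed_match_predict(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    tool: str = "seed-2-8",
    seed_start: int = 1,
    seed_length: int = 7,
) -> PredictionSet:
    """Predict targets by exact seed complementarity.

    A gene is predicted for a miRNA when its 3' UTR contains the reverse
    complement of the miRNA seed (bases ``seed_start``..``seed_start +
    seed_length`` in 0-based coordinates; the default is the canonical
    bases-2-8 7-mer).
    """
    pairs = set()
    for name, mature in mirnas.items():
        if len(mature) < seed_start + seed_length:
            continue
        site = reverse_complement(
            mature[seed_start : seed_start + seed_length].replace("U", "T")
        )
        for gene, utr in utrs.items():
            if site in utr:
                pairs.add((name, gene))
    return PredictionSet(tool, frozenset(pairs))


def pseudo_tool_suite(
    mirnas: dict[str, str], utrs: dict[str, str]
) -> list[PredictionSet]:
    """Four seed-matcher variants standing in for four independent tools.

    The variants use four staggered 7-mer seed windows (bases 1-7, 2-8,
    3-9, 4-10), none containing another, so one chance site supports only
    one tool and chance >= 3-tool consensus needs three distinct co-occurring
    7-mers.  A planted 10-mer site (complement of mature bases 1-10)
    satisfies all four.
    """
    variants = [
        ("tool-A-7mer-1-7", 0, 7),
        ("tool-B-7mer-2-8", 1, 7),
        ("tool-C-7mer-3-9", 2, 7),
        ("tool-D-7mer-4-10", 3, 7),
    ]
    return [
        seed_match_predict(mirnas, utrs, tool, start, length)
        for tool, start, length in variants
    ]


def consensus_targets(
    sets: list[PredictionSet], min_support: int = DEFAULT_MIN_SUPPORT
) -> pd.DataFrame:
    """(miRNA, gene) pairs supported by >= min_support distinct tools."""
    if len(sets) < 2:
        raise ValueError("need at least two prediction sets")
    labels = [s.tool for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tool labels")
    support: dict[tuple[str, str], list[str]] = {}
    for pset in sets:
        for pair in pset.pairs:
            support.setdefault(pair, []).append(pset.tool)
    rows = [
        {
            "mirna": mirna,
            "gene": gene,
            "support": len(tools),
            "tools": ",".join(sorted(tools)),
        }
        for (mirna, gene), tools in support.items()
        if len(tools) >= min_support
    ]
    return pd.DataFrame(
        rows, columns=["mirna", "gene", "support", "tools"]
    ).sort_values(["mirna", "gene"], ignore_index=True)


def hypergeom_upper_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(overlap >= k) drawing n genes from a universe of N with K in the set."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def enrich(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = DEFAULT_ENRICH_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` in each gene set, BH-adjusted.

    Significance is called on the adjusted P at ``alpha`` (default 0.001).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query genes missing from the universe")
    rows = []
    for name, members in gene_sets.items():
        members = members & universe
        k = len(query & members)
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_value": hypergeom_upper_tail(k, len(universe), len(members), len(query)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["adjusted_p"] = []
        df["significant"] = []
        return df
    df["adjusted_p"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["adjusted_p"] < alpha
    return df.sort_values("adjusted_p", ignore_index=True)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted P-values (monotone, order-preserving, <= 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def read_prediction_tsv(path: str | Path) -> list[PredictionSet]:
    """Prediction TSV with columns tool, mirna, gene -> one set per tool."""
    df = pd.read_csv(path, sep="\t")
    missing = {"tool", "mirna", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"prediction file missing columns: {missing}")
    return [
        PredictionSet(tool, frozenset(zip(sub["mirna"], sub["gene"])))
        for tool, sub in df.groupby("tool")
    ]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-like gene sets: name <tab> description <tab> member genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = set(fields[2:])
    return sets


def make_synthetic_target_data(
    mirnas: dict[str, str],
    n_genes: int = 400,
    n_planted: int = 40,
    n_gene_sets: int = 8,
    utr_length: int = 150,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Random 3' UTRs with full 10-mer sites planted for some miRNAs, plus
    gene sets enriched for the planted target genes.

    Synthetic stand-in for external prediction inputs, used by tests and the
    hermetic end-to-end run.  UTRs are kept short relative to the universe
    size so chance seed sites stay a minor fraction of the consensus set and
    the planted pathway is genuinely enriched against the gene universe.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genes = [f"gene-{i + 1:04d}" for i in range(n_genes)]
    utrs = {
        g: "".join(bases[rng.integers(0, 4, utr_length)]) for g in genes
    }
    names = list(mirnas)
    planted_genes = list(rng.choice(genes, size=min(n_planted, n_genes), replace=False))
    for gene in planted_genes:
        mirna = names[int(rng.integers(len(names)))]
        site = reverse_complement(mirnas[mirna][0:10].replace("U", "T"))
        pos = int(rng.integers(0, utr_length - len(site)))
        utr = utrs[gene]
        utrs[gene] = utr[:pos] + site + utr[pos + len(site) :]
    gene_sets: dict[str, set[str]] = {}
    for i in range(n_gene_sets):
        if i == 0:  # one set stacked with planted targets
            members = set(rng.choice(planted_genes, size=max(3, len(planted_genes) // 2), replace=False))
            extra = rng.choice(genes, size=5, replace=False)
            gene_sets["pathway-planted"] = members | set(extra)
        else:
            size = int(rng.integers(8, 25))
            gene_sets[f"pathway-{i:02d}"] = set(rng.choice(genes, size=size, replace=False))
    return utrs, gene_sets
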