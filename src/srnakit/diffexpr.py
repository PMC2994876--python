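"""Two-library digital-expression testing for miRNA counts.

Given one count per miRNA in each of two un-replicated libraries with miRNA
totals N1 and N2, the probability of observing y reads in library 2 given x
in library 1 is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

(the Audic-Claverie digital-expression posterior, generalised to unequal
library sizes).  The two-sided P-value doubles the smallest of the four tail
sums P(Y <= y | x), P(Y >= y | x) and their library-swapped counterparts,
clamped at 1; conditioning on either library alone is not exactly symmetric
under a swap, so both directions are evaluated to treat up- and
down-regulation identically.  Tails are accumulated in log space with
log-gamma terms so P-values far below double-precision tail granularity
(Table-1-scale 1e-127) remain finite.

Relative counts are reads per million miRNA reads; a miRNA is called
differentially expressed when P <= 0.001 and the fold change of relative
counts is >= 2 (both thresholds inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SCALE = 1e6
DEFAULT_P_THRESHOLD = 0.001
DEFAULT_FC_THRESHOLD = 2.0
_TAIL_RELATIVE_CUTOFF = 1e-18


@dataclass(frozen=True)
class LibraryStats:
    """Total miRNA-mapped reads per library (normalisation denominators)."""

    total_lib1: int
    total_lib2: int

    def __post_init__(self):
        if self.total_lib1 <= 0 or self.total_lib2 <= 0:
            raise ValueError("library miRNA totals must be positive")


def normalize_counts(counts: pd.Series | np.ndarray, total: float) -> np.ndarray:
    """Relative counts: reads per million miRNA reads (1e6 * x / N)."""
    if total <= 0:
        raise ValueError("library total must be positive")
    return SCALE * np.asarray(counts, dtype=float) / float(total)


def _log_term(k: int, x: int, log_r: float, log_1pr: float) -> float:
    """log p(k | x) for the digital-expression posterior."""
    return (
        k * log_r
        + math.lgamma(x + k + 1)
        - math.lgamma(x + 1)
        - math.lgamma(k + 1)
        - (x + k + 1) * log_1pr
    )


def _conditional_tails(x: int, y: int, r: float) -> tuple[float, float]:
    """(P(Y <= y | x), P(Y >= y | x)) under the posterior with ratio r."""
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    term_y = math.exp(_log_term(y, x, log_r, log_1pr))
    # lower tail: exact finite sum
    lower = 0.0
    for k in range(y + 1):
        lower += math.exp(_log_term(k, x, log_r, log_1pr))
    if lower < 0.5:
        # the upper tail is the large one; the complement is exact enough
        # and avoids walking to the distribution mode term by term
        upper = 1.0 - lower + term_y
    else:
        # small upper tail: y sits at or past the median, so terms decay
        upper = 0.0
        k = y
        while True:
            term = math.exp(_log_term(k, x, log_r, log_1pr))
            upper += term
            k += 1
            if k > y + 10 and term < _TAIL_RELATIVE_CUTOFF * upper:
                break
            if k > y + 1_000_000:
                break
    return min(lower, 1.0), min(upper, 1.0)


def bayes_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided digital-expression P-value for counts (x, y).

    Symmetric under swapping libraries: bayes_pvalue(x, y, N1, N2) equals
    bayes_pvalue(y, x, N2, N1), because both conditional directions enter
    the doubled-minimum-tail statistic.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    tails = _conditional_tails(x, y, n2 / n1) + _conditional_tails(y, x, n1 / n2)
    return min(1.0, 2.0 * min(tails))


def fold_change(r1: float, r2: float) -> tuple[float, str]:
    """Ratio of the larger to the smaller relative count plus direction.

    Direction is 'up' when library 2 is higher.  Both counts zero is
    undefined and raises.
    """
    if r1 < 0 or r2 < 0:
        raise ValueError("relative counts must be non-negative")
    if r1 == 0 and r2 == 0:
        raise ValueError("fold change undefined when both counts are zero")
    if r2 > r1:
        direction = "up"
    else:
        direction = "down"
    lo, hi = min(r1, r2), max(r1, r2)
    if lo == 0:
        return math.inf, direction
    return hi / lo, direction


def de_table(
    counts: pd.DataFrame,
    stats: LibraryStats | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Full Table-1-style report from a per-miRNA count table.

    ``counts`` needs columns name/count_lib1/count_lib2.  When ``stats`` is
    omitted the normalisation totals are the table's column sums (so relative
    counts sum to one million per library).  For fold changes with one zero
    count, the zero side is floored at the relative count of a single raw
    read; displayed relative counts keep the true zero.
    """
    if counts.empty:
        return pd.DataFrame(
            columns=[
                "name", "count_lib1", "count_lib2", "rel_lib1", "rel_lib2",
                "p_value", "fold_change", "direction", "call",
            ]
        )
    stats = stats or LibraryStats(
        int(counts["count_lib1"].sum()), int(counts["count_lib2"].sum())
    )
    r1 = normalize_counts(counts["count_lib1"], stats.total_lib1)
    r2 = normalize_counts(counts["count_lib2"], stats.total_lib2)
    floor1 = SCALE / stats.total_lib1
    floor2 = SCALE / stats.total_lib2
    rows = []
    for i, row in enumerate(counts.itertuples(index=False)):
        x, y = int(row.count_lib1), int(row.count_lib2)
        if x == 0 and y == 0:
            continue
        p = bayes_pvalue(x, y, stats.total_lib1, stats.total_lib2)
        fc, direction = fold_change(max(r1[i], floor1 * (x == 0)),
                                    max(r2[i], floor2 * (y == 0)))
        rows.append(
            {
                "name": row.name,
                "count_lib1": x,
                "count_lib2": y,
                "rel_lib1": r1[i],
                "rel_lib2": r2[i],
                "p_value": p,
                "fold_change": fc,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    return call_differential(df, p_threshold, fc_threshold)


def call_differential(
    results: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Add up/down/unchanged calls (P <= threshold AND FC >= threshold)."""
    df = results.copy()
    significant = (df["p_value"] <= p_threshold) & (df["fold_change"] >= fc_threshold)
    df["call"] = np.where(significant, df["direction"], "unchanged")
    return df


def de_tallies(called: pd.DataFrame) -> dict[str, int]:
    return {
        "up": int((called["call"] == "up").sum()),
        "down": int((called["call"] == "down").sum()),
        "unchanged": int((called["call"] == "unchanged").sum()),
    }


def aggregate_mirna_counts(classified_frame: pd.DataFrame) -> tuple[pd.DataFrame, LibraryStats]:
    """Aggregate classified tags to per-catalog-miRNA counts.

    Only tags in the miRNA category enter the normalisation totals; only tags
    attributed to a catalog mature (isomiR window) enter the per-name table.
    """
    mirna = classified_frame[classified_frame["category"] == "miRNA"]
    if mirna.empty:
        raise ValueError("no miRNA-category tags to aggregate")
    stats = LibraryStats(
        int(mirna["count_lib1"].sum()), int(mirna["count_lib2"].sum())
    )
    named = mirna[mirna["matched_name"] != ""]
    table = (
        named.groupby("matched_name", as_index=False)[["count_lib1", "count_lib2"]]
        .sum()
        .rename(columns={"matched_name": "name"})
        .sort_values("name", ignore_index=True)
    )
    return table, stats
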