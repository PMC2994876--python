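"""2^-ddCt qPCR fold changes and concordance with sequencing.

Ct tables carry one row per (miRNA, sample, replicate) with the target Ct
and the U6 snRNA reference Ct.  Replicates are averaged on the Ct scale,
dCt = mean(Ct_target) - mean(Ct_U6) per sample, ddCt = dCt_B - dCt_A and the
fold change of sample B relative to sample A is 2^-ddCt.  Concordance
between sequencing and qPCR fold changes is the Pearson correlation of
paired log2 fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

CT_COLUMNS = ["mirna", "sample", "ct_target", "ct_reference", "replicate"]


def _validate_ct(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value")
    bad = ~records[["ct_target", "ct_reference"]].apply(
        lambda col: (col > 0) & (col < 45)
    ).all(axis=1)
    if bad.any():
        raise ValueError("Ct values must lie in (0, 45)")
    return records


def ddct_fold_change(
    records: pd.DataFrame, mirna: str, sample_a: str, sample_b: str
) -> float:
    """2^-ddCt fold change of ``sample_b`` relative to ``sample_a``.

    Invariant to adding a constant to every Ct of one sample (the reference
    normalisation cancels it); log2 of the result is antisymmetric under
    swapping the samples.
    """
    records = _validate_ct(records)
    sub = records[records["mirna"] == mirna]
    dct = {}
    for sample in (sample_a, sample_b):
        rows = sub[sub["sample"] == sample]
        if rows.empty:
            raise ValueError(f"no Ct records for {mirna!r} in sample {sample!r}")
        dct[sample] = rows["ct_target"].mean() - rows["ct_reference"].mean()
    ddct = dct[sample_b] - dct[sample_a]
    return float(2.0 ** (-ddct))


def ddct_table(records: pd.DataFrame, sample_a: str, sample_b: str) -> pd.DataFrame:
    """Per-miRNA fold-change table for all miRNAs present in both samples."""
    records = _validate_ct(records)
    rows = []
    for mirna in sorted(records["mirna"].unique()):
        sub = records[records["mirna"] == mirna]
        if not {sample_a, sample_b} <= set(sub["sample"]):
            continue
        fc = ddct_fold_change(records, mirna, sample_a, sample_b)
        rows.append({"mirna": mirna, "fold_change": fc, "log2_fold_change": np.log2(fc)})
    return pd.DataFrame(rows)


def concordance(seq_log2fc: pd.Series, qpcr_log2fc: pd.Series) -> float:
    """Pearson correlation of paired signed log2 fold changes."""
    x = np.asarray(seq_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired fold changes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in fold changes")
    return float(pearsonr(x, y)[0])


def simulate_concordance_experiment(
    n_mirnas: int = 29,
    target_r: float = 0.9,
    signal_sd: float = 2.0,
    seed: int = 0,
    sample_a: str = "lib1",
    sample_b: str = "lib2",
) -> tuple[pd.Series, pd.DataFrame]:
    """Synthetic paired experiment with a planted expected correlation.

    Sequencing log2 fold changes are N(0, signal_sd^2); qPCR repeats them
    plus Gaussian noise whose variance is set so the population correlation
    equals ``target_r``.  Returns the sequencing log2 FCs and a Ct table
    (triplicates, U6-normalised) that reproduces the noisy values through
    the 2^-ddCt route.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    noise_sd = signal_sd * np.sqrt(1.0 / target_r**2 - 1.0)
    seq = rng.normal(0.0, signal_sd, n_mirnas)
    qpcr = seq + rng.normal(0.0, noise_sd, n_mirnas)
    rows = []
    for i in range(n_mirnas):
        name = f"mir-{i + 1:03d}"
        # ddCt = -log2 FC; put all signal in the target Ct of sample B
        for rep in range(3):
            rows.append(
                {"mirna": name, "sample": sample_a, "ct_target": 25.0,
                 "ct_reference": 20.0, "replicate": rep}
            )
            rows.append(
                {"mirna": name, "sample": sample_b, "ct_target": 25.0 - qpcr[i],
                 "ct_reference": 20.0, "replicate": rep}
            )
    seq_series = pd.Series(seq, index=[f"mir-{i + 1:03d}" for i in range(n_mirnas)])
    return seq_series, pd.DataFrame(rows)
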