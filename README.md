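# srnakit

Small RNA-seq tag profiling for two-library comparisons: read cleaning and
tag collapsing, mismatch-tolerant genome mapping with hierarchical
annotation, an exact Bayesian test for differential expression between two
un-replicated libraries, hairpin-based discovery of novel miRNA candidates,
miRNA-target consensus with gene-set enrichment, and 2^−ΔΔCt qPCR
concordance. A synthetic-data module generates complete two-library
experiments with planted ground truth, so the entire pipeline runs and is
validated hermetically — no downloads, no external tools.

The package is aimed at the classic deep-sequencing study design that
compares the small-RNA transcriptomes of two related cell states (for
example an androgen-dependent prostate-cancer line against its
androgen-independent derivative) with one library per condition.

## The statistics at the core

**Digital expression test.** With `x` reads for a miRNA among `N₁` total
miRNA reads in library 1 and `y` among `N₂` in library 2, the probability of
the second observation given the first is the posterior predictive

```
p(y | x) = (N₂/N₁)^y · (x+y)! / ( x! · y! · (1 + N₂/N₁)^(x+y+1) )
```

— a negative-binomial NB(x+1, 1/(1+N₂/N₁)) distribution that accounts for
the sampling variability of low counts. The two-sided P-value doubles the
smallest of the four tail sums (both conditionals, both directions), clamped
at 1. Tails are accumulated in log space, so P-values down to 1e-127 and
below remain finite. A miRNA is called differentially expressed when
P ≤ 0.001 and the fold change of relative counts (reads per million miRNA
reads) is ≥ 2.

**Hairpin discovery.** Mapped tags touching no annotation are folded with
100 nt of flanking genomic sequence under a Zuker-style minimum-free-energy
dynamic programme (nearest-neighbour stacking with G·U wobble pairs, loop
penalties, multiloop costs). A candidate is accepted when the tag lies
wholly on one arm of a single stem-loop, ≥ 16 of its bases are paired, the
precursor spans 60–100 nt and its MFE is ≤ −18 kcal/mol.

**Targets and enrichment.** (miRNA, gene) predictions from ≥ 3 of 4
independent tools form the consensus target set; gene-set enrichment is the
upper-tail hypergeometric probability with Benjamini–Hochberg adjustment
(significant at adjusted P < 0.001).

## A worked example

```python
from srnakit.diffexpr import bayes_pvalue, fold_change

ratio, direction = fold_change(290.95, 5977.41)
print(f"{ratio:.2f} ({direction})")      # 20.54 (up)
print(bayes_pvalue(5, 0, 1_000_000, 1_000_000))  # 0.03125
```

The first call reproduces a published fold change from its printed relative
counts: the miRNA is 20.54-fold higher in the second library. The second
shows why low counts need an exact test — 5 reads against 0 at equal depths
only reaches P = 0.03125 (2·1/64), far short of the 0.001 calling threshold.

Running the whole pipeline on simulated libraries:

```bash
srnakit all --work-dir run --seed 11 --n-reads 100000
```

writes, under `run/`, the collapsed tag table, the per-category composition
(miRNA ≈ 65%/62% of mapped reads, ≈ 94% of reads mapped), the insert-length
histogram (mode 22 nt in both libraries), the differential-expression table
(40 up, 40 down at the planted folds with zero false calls among nulls), the
novel-candidate table (all ten planted hairpins, with their shared /
library-specific partition recovered exactly), the consensus-target and
enrichment reports, and a qPCR concordance table (Pearson r ≈ 0.91 at the
planted correlation 0.9). Each stage is also available as its own
subcommand (`simulate`, `preprocess`, `annotate`, `diffexp`, `novel`,
`targets`, `qpcr`) and, equivalently, as library calls — see `examples/`
for one short script per capability.

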