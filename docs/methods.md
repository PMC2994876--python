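# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Read cleaning and tag collapsing

Reads pass four stages in fixed order: quality filter → 3′ adapter trim →
length retention → collapse. Each stage partitions its input exactly, and
the per-stage discard tally is reported.

- **Quality filter** retains a read iff its N count is ≤ `max_n` (default 0)
  and its mean Phred score is ≥ `min_mean_quality` (default 20), both
  boundaries inclusive. The thresholds are deliberately simple: the upstream
  protocol only promises that "low-quality reads are removed", so the filter
  is a clean, documented rule rather than an instrument model.
- **Adapter trimming** takes the insert before the leftmost occurrence of
  the 3′ adapter. Mid-read occurrences must match the full adapter; at the
  read end a prefix of ≥ `min_adapter_overlap` nt (default 8) counts. Reads
  with no adapter evidence are dropped rather than kept untrimmed: a genuine
  ≤ 30-nt insert on these layouts always runs into adapter, so an untrimmable
  read is either artefactual or longer than the assay window. Trimming is
  exact-match; error-tolerant matching is deliberately not attempted
  (at 8+ nt of required overlap, a sequencing error in the adapter costs a
  read but never corrupts a tag).
- **Length retention** keeps inserts of 18–30 nt, both endpoints inclusive.
- **Collapse** counts identical inserts per library into unique tags,
  ordered by descending total count with lexicographic tie-break, making the
  table deterministic.

The 5′ adapter is assumed removed by the instrument (single-end small-RNA
layout, reads start at insert base 1); only the 3′ adapter contaminates
reads. Reads and adapters are handled as DNA (T, not U) because basecallers
emit DNA.

## Mapping

Tags map ungapped to both strands with ≤ 2 mismatches, exhaustively: every
qualifying placement is reported in forward coordinates. The search splits
the tag into three disjoint seed chunks (pigeonhole: two mismatches leave at
least one chunk exact), looks chunks up in lazily built k-mer position
indexes, and verifies candidates base by base. Reference positions outside
ACGT never match. The contract — set identity with an exhaustive offset
scan — is asserted in tests against an independent vectorised scan.
Placements per tag are capped at 20 in reports (the cap is flagged); a tag's
counts are assigned once to its category, never split across placements.

## Annotation cascade

Each mapped tag receives the first category its placements touch in the
priority order miRNA > ncRNA > repeat > mRNA (config-overridable); mapped
but untouched tags are *unclassified*, unmapped tags *unmapped*. A placement
touches a category when ≥ 50% of the tag's bases fall inside an interval of
that category on the same strand; repeats are strand-agnostic (repeat-derived
small RNAs arise from both strands). Classification is a function of the
overlap set only — annotation file order never changes the result.

A miRNA-category tag is attributed to a catalog mature when it aligns within
the precursor on the mature's strand and its 5′ end is within ± 3 nt of the
catalog mature 5′ end (isomiR window); matched names drive the per-miRNA
count table, while unmatched miRNA-category tags still count toward the
miRNA normalisation total.

## Differential expression

Counts are normalised to reads per million miRNA reads; with the totals
taken from the aggregated table, per-library relative counts sum to one
million. The digital-expression posterior

p(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^{x+y+1})

is evaluated in log space (log-gamma terms). The finite lower tail is summed
exactly; the upper tail is summed term by term when it is the small tail and
taken as the complement otherwise, with summation stopping when a term falls
below 1e-18 of the accumulated mass. The two-sided P doubles the smallest of
the four tails from both conditional directions: conditioning on one library
alone is not swap-symmetric, and the symmetrised statistic treats up- and
down-regulation identically (it agrees with the single-conditional version
wherever that version is itself symmetric). Calls require P ≤ 0.001 **and**
fold change ≥ 2, both inclusive; no multiple-testing correction is applied
in calling (correction enters only in enrichment). For fold changes with one
zero count the zero side is floored at the relative count of a single raw
read, avoiding infinite ratios while displayed relative counts keep the true
zero. P-values in reports use scientific notation with exact zeros printed
as `0`.

## RNA folding

Minimum-free-energy nested structures over Watson–Crick and G·U pairs, via
the classic V/WM/W recursion with traceback. The energy model is a
simplified nearest-neighbour table: stacking energies per adjacent pair
type; hairpin, bulge and internal-loop penalties tabulated to size 6–9 and
extrapolated logarithmically; an affine multiloop cost (3.4 close + 0.4 per
branch + 0.1 per unpaired base); minimum hairpin loop 3 nt; bulge/internal
loops capped at 30 unpaired bases; no pseudoknots; lonely pairs permitted
(the model has no non-canonical-helix penalty, so forbidding them would be a
separate structural constraint, not an energy term); exterior bases free —
hence the MFE never increases when bases are appended, and MFE = 0 iff the
structure is empty. The DP fill is numba-compiled (the ~220-nt candidate
windows each fold in ~20 ms); traceback re-derives decisions in Python from
the filled matrices with a 1e-6 tolerance. `score_structure` evaluates the
same decomposition on an explicit pair set, so emitted structures can be
re-scored and the DP is cross-checked against exhaustive enumeration of all
nested structures for sequences up to 30 nt. The parameter table is a
plausible simplification, not a fit to measured thermodynamics: *structural*
correctness (optimum under the stated model) is the validated claim, not
numeric agreement with any particular published folding engine.

## Novel miRNA discovery

Unclassified tags with ≥ `min_candidate_reads` (default 5) total reads are
examined at each placement: the window of 100 nt flanking each side (clipped
at chromosome ends, reverse-complemented for minus-strand placements so the
tag reads 5′→3′) is folded, and the stem-loop harbouring the tag is located
by walking outward from each hairpin tip while the enclosing loop stays
single-branched with ≤ `max_stem_gap` (default 6) unpaired bases per step.
When random flanking sequence extends a stem past the precursor-length cap,
the walk backs down the chain to the widest enclosing pair within the cap
that still covers the mature — precursors above ~100 nt are not biologically
plausible pre-miRNAs, so the cap is part of the precursor definition rather
than a filter. The trimmed span is refolded and must pass, in order:
mature length 20–24; a single stem-loop; mature wholly on one arm (5′ arm if
it precedes the terminal loop, else 3′); ≥ 16 mature bases paired; MFE ≤ −18
kcal/mol; precursor length 60–100 nt. Rejections report the first failed
criterion. Every emitted call is independently re-validated by refolding the
reported genomic interval from scratch.

Candidates are deduplicated by precursor interval (keeping the more stable
fold), named in genomic order, normalised per million mapped reads, and
partitioned into shared / library-1-only / library-2-only by observed
expression; candidates with normalised frequency > 10 are flagged
validation-eligible. A designed hairpin can be recovered from either strand
(its reverse complement is also a hairpin); interval-level deduplication
collapses the two views, and the arm label follows the kept orientation.

## Targets and enrichment

External predictions are consumed as (tool, miRNA, gene) TSV; the built-in
seed matcher exists so the full pipeline runs hermetically. Its four
pseudo-tool variants use staggered 7-mer seed windows (mature bases 1–7,
2–8, 3–9, 4–10) — none contains another, so a single chance site supports
only one tool, while a planted 10-mer site (complement of bases 1–10)
supports all four. Consensus keeps pairs in ≥ 3 distinct tools. Enrichment
is the hypergeometric upper tail P(overlap ≥ k) against the universe of all
genes in the supplied UTR/gene-set files, Benjamini–Hochberg adjusted across
the tested sets, significant at adjusted P < 0.001. The synthetic target
data keep UTRs short (150 nt) relative to the universe (400 genes) so chance
seed sites stay a minor fraction of the consensus and the planted pathway is
genuinely enriched.

## qPCR concordance

Replicates are averaged on the Ct scale; ΔCt = mean Ct_target − mean Ct_U6
per sample, ΔΔCt = ΔCt_B − ΔCt_A, fold change = 2^−ΔΔCt. The estimate is
invariant to adding a constant to all Ct values of one sample, and its log2
is antisymmetric under swapping samples. Concordance is the Pearson
correlation of paired signed log2 fold changes (≥ 3 pairs, defined variance
required). The synthetic concordance experiment draws sequencing log2 fold
changes from N(0, 2²) and adds Gaussian noise with σ = 2·√(1/r² − 1) so the
population correlation equals the planted r; the noisy values are encoded
into a triplicate Ct table and recovered through the ΔΔCt route.

## The synthetic experiment

The generator builds a ~70-kb two-chromosome genome carrying 200 miRNA
precursors (70–90 nt, catalogued matures of 20–24 nt with mode 22, both
strands, both arms), ncRNA/repeat/mRNA intervals as degradation sources, and
ten designed novel hairpin loci, then samples two libraries of 100,000 reads
(40-nt reads = insert + 3′ adapter + padding; per-base error 0.001; 0.5% of
reads marked low-quality).

Defaults are calibrated to the published library pair the pipeline is
modelled on: per-library category mixtures put the mapped fraction at
94.2%/93.6% of retained reads and the miRNA share at 65.2%/62.3% of mapped
reads; insert lengths follow a discretised Laplace around 22 nt within the
15–30-nt gel window (only the junk category carries the sub-18-nt tail, and
its sampling weight is corrected for length-filter truncation so the
retained composition hits the targets exactly in expectation); 40 up- and 40
down-regulated miRNAs are planted at log-uniform 4–25× with unit base
abundance and mirrored fold lists, so the within-miRNA composition stays
balanced — without that balance, normalising to total miRNA reads would
shift every null miRNA and manufacture false calls. Null miRNA abundances
are log-normal (σ = 0.8). Novel loci default to 4 shared + 3 per
library-specific class.

Planted hairpins are designed, not sampled: arms are exact reverse
complements except for three substitutions opposite the mature, chosen at
positions and bases such that they read as G·U wobbles in transcript
orientation — the mature tag then maps uniquely (3 DNA mismatches from the
far arm) while the stem still folds as a single helix. Wobble pairing is not
strand-symmetric, so the substitution table depends on the locus strand. The
mature sits ≥ 3 bp interior to its arm (terminal fraying otherwise strips
edge bases), and the terminal loop is purine-only, which cannot self-pair in
either orientation.

What the generator does **not** emulate: PCR duplication and ligation bias,
instrument-specific error and quality profiles, isomiR heterogeneity
(each miRNA yields one exact mature sequence plus uniform sequencing error),
multi-mapping repeat families (the genome is random, so fragment species map
uniquely), spliced or gapped alignments, and real miRNA sequence families.
Passing the recovery tests therefore demonstrates that the pipeline's
inference is correct under its stated model — not that the thresholds are
optimal for any particular real library.

## Determinism and problem sizes

All randomness flows from a single integer seed (reference, reads, truth
table, every synthetic stand-in); a fixed seed reproduces every output file
byte for byte. The shipped validation uses two libraries of 10⁵ reads, a
50-kb genome for mapper/oracle comparisons (200 tags), 100 sequences of
≤ 30 nt for the folding oracle, a 500-case grid for the Bayesian-test oracle
with a 10⁴-miRNA null calibration at 10⁵ reads per library, and 100 seeds
for the qPCR concordance distribution — sizes at which every check runs in
seconds while sampling error stays far inside the asserted tolerances.
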