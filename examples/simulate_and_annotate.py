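"""Simulate two small-RNA libraries, clean the reads and annotate the tags.

Prints the insert-length histogram mode and the per-category composition of
mapped reads — the two standard first-look summaries of a small-RNA library.
"""

import tempfile

from srnakit.annotate import histogram_mode, length_distribution, summarize_categories
from srnakit.config import PipelineConfig
from srnakit.pipeline import Pipeline
from srnakit.simulate import SimulationConfig

with tempfile.TemporaryDirectory() as work:
    pipe = Pipeline(PipelineConfig(seed=7, n_reads=20_000), work)
    pipe.simulate(SimulationConfig(seed=7, n_reads=20_000))
    tags = pipe.preprocess()
    classified = pipe.annotate()

print(f"\nunique tags after collapsing: {len(tags)}")

hist = length_distribution(classified)
print("\ninsert-length histogram (reads):")
print(hist.to_string(index=False))
print(
    f"modal insert length: {histogram_mode(hist, 'lib1')} nt (library 1), "
    f"{histogram_mode(hist, 'lib2')} nt (library 2)"
)
# ~22 nt is the Dicer-product signature: most reads are genuine miRNAs

summary = summarize_categories(classified)
print("\ncategory composition (fraction of mapped reads):")
print(summary.round(4).to_string(index=False))
# miRNA should dominate (~0.62-0.65); 'mapped_fraction' is the share of
# retained reads that aligned to the reference with <= 2 mismatches (~0.94)
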