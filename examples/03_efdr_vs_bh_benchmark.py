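"""Scaled-down benchmark: empirical FDR versus Benjamini-Hochberg.

Synthesises an interdependent ontology (entries share a common gene pool),
plants source entries whose genes form a noisy target set, and measures
how often each correction recovers the sources.  A short run; the full
protocol (100 iterations per noise ratio) lives in scripts/acceptance.py.
"""

from setenrich import (
    BenchmarkConfig,
    OverlapSpec,
    generate_overlapping_ontology,
    pairwise_overlap_stats,
    run_benchmark,
)

spec = OverlapSpec(mean_pairwise_overlap=16.0)  # the high-dependence regime
collection = generate_overlapping_ontology(spec, seed=11)
print(
    f"ontology: {len(collection)} entries, "
    f"mean pairwise overlap {pairwise_overlap_stats(collection).mean:.2f}"
)

config = BenchmarkConfig(
    iterations=20, efdr_resamples=1000, noise_ratios=(0.0, 0.3), seed=3
)
results, summary = run_benchmark(collection, config)
print(summary.round(4).to_string(index=False))
print(
    "\nmean_tpr_*: fraction of planted source entries recovered at "
    "alpha=0.05; the eFDR consistently recovers more than BH, and the "
    "one-sided paired t-test p-value quantifies the gain."
)
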