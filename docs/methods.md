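# Methods

## Overrepresentation model

For each ontology entry the 2×2 table is formed from the *effective* sets:
the background is deduplicated, the target is restricted to the background
(identifiers outside it are dropped with a warning), and entry members are
intersected with the background.  With background size `N`, entry coverage
`K`, effective target size `n` and overlap `k`, the reported p-value is the
hypergeometric upper tail `P(X ≥ k)` (SciPy's survival function), i.e. the
one-tailed Fisher exact test.  Only overrepresentation is tested.

Entries with zero overlap — and even entries with `K = 0` after background
intersection — are retained with `p = 1` rather than dropped.  This keeps
the rank universe `J` identical between the observed run and every eFDR
resampling step, which the rank-based estimator requires; callers who want
them gone should size-filter first (`filter_collection`).

Identifiers are opaque, case-sensitive strings throughout; no mapping
between identifier namespaces is attempted.

## The empirical FDR

The eFDR is the plug-in FDR estimate (expected null discoveries over
observed discoveries) with each entry's own p-value as the threshold:

* observed ranks use the tie-maximum convention
  `R_j = #{i : p_i ≤ p_j}`, so tied p-values always share a rank and
  hence an eFDR;
* each of `S` resampling steps draws a uniform random subset of the
  background, without replacement, of size `n` (a simulated target),
  recomputes all `J` p-values, and counts `R_j^s = #{i : p_i^s ≤ p_j}`;
* `eFDR_j = min(R̄_j / R_j, 1)` with `R̄_j` the mean of `R_j^s` over steps.

Two conventions deserve note.  First, the ratio is *expected over
observed*; the reciprocal is not an FDR (it would exceed 1 exactly for
unenriched entries, the opposite of the truncation direction).  Second,
`R_j^s` counts null p-values against the **observed** `p_j`, not the rank
of entry `j` within the resampled vector: the latter is ≈ `(J+1)/2` for
every entry regardless of enrichment and carries no signal.  A degenerate
but reassuring consequence of the counting definition: if a simulated
target happens to reproduce the real one, `R_j^s = R_j` exactly.  For a
single-entry collection the eFDR reduces to the empirical probability of a
null p-value at or below the observed one — the resampling p-value, as it
should.

The observed test is not included among the `S` resamples (no "+1"
pseudo-count); with the recommended `S ≥ 10 000` the difference is
negligible, and `S` is exposed everywhere (`resamples=`,
`--permutations`).  The simulation benchmark uses `S = 1000` per run,
matching its protocol.

Implementation: one boolean membership matrix (entries × background) and
one p-value lookup table `P(X ≥ k)` for `k = 0..n` per entry are
precomputed; each resampling step is a fancy-indexed overlap count, a table
lookup and a sorted-vector rank count.  Observed p-values are read from the
same lookup table so float ties between observed and null values are
exact.  A single seeded `numpy` generator drives the draws, one per step,
in order: results are bit-reproducible from `(seed, S)`.  The `threads`
field on `EfdrConfig` is a compatibility hint; the loop is a single
vectorised stream (per-step work is a handful of numpy ops on `J ≤` a few
hundred entries, where a thread pool would cost more than it saves), so
determinism across thread counts holds trivially.

No monotonicity (step-up) smoothing is applied across entries: the raw
plug-in estimate is reported per entry, truncated at 1.

## Classical corrections

Bonferroni and Benjamini–Hochberg are delegated to
`statsmodels.stats.multitest.multipletests` behind a thin array-in /
array-out interface; the test suite cross-checks them against hand-rolled
closed forms.  The guaranteed ordering `bonferroni ≥ BH ≥ raw` holds
elementwise.

## GMT handling

Both dialects are auto-detected per row: ≥4 tab fields is the MSigDB
layout (members in columns 3..end); exactly 3 tab fields with spaces in
the third column is the space dialect.  Duplicate member tokens within a
row are dropped keeping the first occurrence, so entry sizes are
well-defined for the hypergeometric model; a duplicated `ontology_id` is a
parse error.  `#` header lines round-trip; `key: value` comments are
additionally indexed into the collection's metadata mapping.

Size filtering is inclusive on both bounds ("exclude fewer than min and
more than max").  Size is counted after background intersection by default
when a background is supplied — that is the size the test statistic sees —
with `scope="raw"` available for file-level curation.

## GSEA

The ranked-list method is the classic weighted Kolmogorov–Smirnov running
sum: walking down the list sorted by score (descending by default, stable
under ties), hits add `|score|^w` normalised over the set's hits and misses
subtract `1/(L − n_hits)`; the enrichment score is the signed maximum
deviation from zero.  `w = 1` by default, `w = 0` gives the unweighted KS
form.  If every hit's score is zero the hit weights fall back to equal; if
the set covers the whole list there are no misses and `ES = 1`.

The permutation null randomises gene labels: `n_perm` random same-size
identifier subsets are scored, and the p-value uses the sign-matched
portion of the null with add-one smoothing,
`p = (1 + #{ES* ≥ ES}) / (1 + #{ES* ≥ 0})` for `ES ≥ 0` and symmetrically
for negative scores.  Normalising by the same-sign count (rather than all
`n_perm`) is the classic convention and makes the p-values of unenriched
sets uniform, which the test suite verifies by KS test.  Per-entry
permutation streams are derived from the run seed and the entry's row
index, so tables are reproducible and independent of evaluation order.
Entries with no member in the list are untestable and skipped; BH is
applied across the tested rows.  NES normalisation, multilevel p-value
refinement and leading-edge extraction are out of scope.

## Synthetic benchmark

The benchmark reproduces, at desk scale, the comparison of eFDR against BH
on interdependent ontologies.

**Generator.**  `generate_overlapping_ontology` builds a collection whose
mean pairwise overlap (shared genes per entry pair) hits a requested
value.  Entry sizes follow a deterministic log-spaced ladder over
`genes_per_entry` (default 5–200): real regulon collections are heavily
skewed, with many small regulons and a few hubs, and the small entries are
exactly where discrete p-values make correction behaviour interesting.
A fraction `shared_fraction` (default 0.9) of each entry's genes comes
from a common pool of `P` genes, included with probability
`q_j = min(1, f·size_j/P)`; the remainder are entry-private.  Expected
pair overlap is `P·q_i·q_j`, and `P` is solved numerically (largest root)
so the mean over all pairs matches the target; the per-collection mean is
within 15% of the target, which the tests check via
`pairwise_overlap_stats` (exact over all pairs).  Hubs can absorb the
entire pool — as the largest regulons do in real collections.  The
defaults (50 entries, overlap 16 for the high-dependence regime versus 1
for the low one, universe cap 8000) mirror the contrast between a highly
overlapping transcription-factor collection and a sparsely overlapping
one.

**Protocol.**  Per iteration: 20% of entries are drawn as sources
(re-drawn each iteration, giving i.i.d. repeats), the core target is a
uniform 85% subsample of the union of source genes (ceiling rounding), and
noise adds `⌈ratio·|core|⌉` genes drawn from ontology genes outside every
source entry — a pool that keeps "false positive" well-defined.  ORA runs
with the union of all ontology genes as background; an entry is
significant when its eFDR or BH value is `< alpha` (0.05).  TPR and FPR
are exact ratios over sources and non-sources.  Per-(ratio, iteration)
RNG streams are spawned from the master seed, so any grid subset is
reproducible in isolation.  The summary reports per-ratio means plus the
one-sided paired t-test on the per-iteration TPR difference (eFDR − BH).

**What the benchmark does and does not show.**  On the high-overlap
geometry the eFDR recovers consistently more planted sources than BH at
every noise ratio, and the gap shrinks on the low-overlap geometry — the
qualitative behaviour expected of the plug-in estimator, driven by the
attainable (discrete, dependent) null that BH's uniform assumption
ignores.  The synthetic geometry is deliberately stylised: gene-pool
sharing is homogeneous rather than hierarchical, sizes are a smooth
ladder, and in the high-overlap regime non-source entries genuinely absorb
target genes through the shared pool, so label-based FPR is high for
*both* methods and is meaningful only comparatively.  Passing the
benchmark demonstrates the estimator's behaviour under dependence, not
calibration on any particular real ontology.

## Numerical and scale choices

* Hypergeometric tails are clamped into `[0, 1]` against survival-function
  round-off; exactness to the combinatorial tail sum is verified to 1e-12
  relative error over the full `N ≤ 25` grid.
* Tie handling is exact everywhere by construction (shared lookup tables,
  `searchsorted` rank counts).
* Default `S = 10 000` for analyses; the benchmark protocol uses
  `S = 1000`, 250 iterations per noise ratio, ratios 0/0.1/0.2/0.3 — large
  enough for stable means and well-powered paired tests, small enough to
  run in a few minutes on one CPU.
* The complete-null calibration check uses 500 independent uniform targets
  of size 60 with `S = 200`; the measured discovery rate at 0.05 is well
  under 0.01 (the estimator is conservative under the complete null, as a
  plug-in FDR should be).
* Derived seeds are spawned via `numpy.random.SeedSequence` and kept below
  2^31.

## Known limitations

* Depletion (lower tail) is not tested; no effect sizes beyond the counts.
* The eFDR needs the whole collection to be tested jointly; filtering
  after the fact changes ranks and is not supported (filter first).
* GSEA p-values are plain permutation estimates; very small p requires
  large `n_perm`.
* The generator's overlap target is a mean over pairs; the realised
  distribution is binomial around it, not matched in higher moments.
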