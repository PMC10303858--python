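# Methods

## Scope and model

`l1locus` implements a replicate-free differential-expression workflow for
locus-level transposable-element (full-length LINE-1) expression, plus the
downstream genomic-context, enrichment, exonization and profiling statistics
that interpret it. The package operates strictly downstream of read alignment
and counting: inputs are count matrices, interval annotations, fragment
tables and signal tracks. Alignment, locus-level TE quantification,
replicate-based negative-binomial DE testing, intron-retention quantification
and peak calling are out of scope.

### Coordinates

All in-memory coordinates are 0-based, half-open (BED-native). GTF, the only
1-based inclusive format touched, is converted on read and write. Every
converter is exercised on 1-bp features in the test suite; using a single
internal convention removes off-by-one drift between modules.

### Normalization

Size factors follow the median-of-ratios recipe: the per-feature reference is
the geometric mean across samples, computed in log space; features with any
zero count are excluded from the reference (log of zero is undefined, and
excluding such features is the standard behavior of this estimator); a
sample's factor is the median of its count/reference ratios. Normalized
values are raw counts divided by the sample's factor. Requesting factors from
a matrix with no all-positive feature is an error instructing the caller to
pre-filter.

### Per-sample z-scores

For case sample *j* and feature *i*,

    z_ij = (x_ij − mean(x_i,controls)) / sd(x_i,controls)

on normalized linear-scale values (not log counts — the statistic is defined
directly on normalized expression). Control samples are scored leave-one-out
against the remaining controls, so no observation enters its own reference
distribution; at least 3 controls are required. `sd` uses the n−1 denominator
by default (the conventional estimator; a `ddof=0` switch is exposed because
the choice is not dictated by the statistic's definition). Features whose
control sd is zero are `undefined` and never counted as differentially
expressed. The DE rule is strict: `up` iff z > 3, `down` iff z < −3.

No multiple-testing correction is applied — the method is a fixed-threshold
outlier screen, not a calibrated test. Instead, reports annotate the expected
number of null calls per case sample: with n controls, (x − x̄)/s is
t-distributed with n−1 degrees of freedom after a √(1 + 1/n) inflation, so
the expected count is `n_features · 2 · P(T_{n−1} > 3/√(1+1/n))` (about 6
calls among ~290 expressed genes at n = 9). This is also why the per-sample z is
deliberately reported as exploratory: with 9 controls the |z| > 3 null rate
is ≈ 2.2%, far above the Gaussian 0.27%.

Log2 fold changes are `log2((x+ε)/(mean_ctrl+ε))` with ε = 1 by default;
zero handling is not dictated by the ratio's definition, and a unit
pseudocount keeps low counts conservative. Net upregulation per sample is
`#(z > 3) − #(z < −3)`.

### Expression and annotation filters

Expressed L1 loci: mean raw count across all samples ≥ 200 (inclusive),
length strictly > 5000 bp, subfamily in the young-subfamily whitelist
(`L1HS`, `L1PA*`). Expressed genes: mean raw count ≥ 200 by default; the
threshold is configurable (a 15-read variant is sometimes appropriate for
gene-level screens, so nothing is hard-coded). Retained-intron records are
kept iff `IRratio ≥ 0.1`, `IntronDepth ≥ 3` (both inclusive), no warning
flag, and no overlap with a known feature. MilliDiv summaries report the
per-subfamily arithmetic mean for all loci and for the expressed subset.

### Interval arithmetic

A small sort/searchsorted engine provides bedtools-like semantics: overlap
iff ≥ 1 shared bp (half-open), exact per-chromosome subtraction
(introns = gene bodies minus exons), closest-feature queries (overlap →
distance 0; bookended intervals → 1; ties broken by smaller start, then id),
and 100%-containment fragment counting, optionally per spliced block. All
operations are strand-blind, matching the unstranded overlap convention of
the analysis it supports. Equivalence with per-base brute-force membership
oracles is asserted in the test suite on randomized instances.

Context classification: an L1 is `exonic` with ≥ 1 bp exon overlap, else
`intronic` with ≥ 1 bp intron overlap, else `intergenic`. Exon precedence is
a design choice (exon contact is the stronger claim when an element touches
both); a flag switches to larger-overlap-wins. Host gene = overlapping gene
with maximal overlap, ties to the smaller start. Anticorrelated genes are
genes with negative z hosting an intronic L1 with z > 3 — the L1 side has a
threshold, the gene side only a sign.

### Resampling enrichment

Observed = |target ∩ annotation|; the null is the overlap of n (default
1000) uniform, without-replacement, size-matched draws from the
expressed-gene universe; the score is (obs − null mean)/null sd, undefined
when the null is degenerate. Because the null count is exactly
hypergeometric, the exact hypergeometric p-value is reported alongside as an
internal cross-check — it is an addition of this implementation, flagged as
such in the output schema. A genomic variant counts L1 loci overlapping any
gene of a set and swaps in random gene sets.

### Shared-fragment exonization statistic

For loci A and B: (1) collect read ids of proper pairs with mapq ≥ 30 having
≥ 1 mate fully contained in A; (2) total fragments = all mates of those ids
(two per id); (3) shared ids = those with ≥ 1 mate overlapping B by ≥ 1 bp;
pct = 100·shared/total. The asymmetry (containment on the A side,
any-overlap on the B side) follows the statistic's definition: extraction
"within the boundaries" of A, intersection with B. A pair perfectly split
across A and B scores 50%, the statistic's ceiling for a single pair.
Distributions are built for three pairings — random expressed exons vs their
closest exon, upregulated L1s vs their closest exon, random fixed-length
segments inside expressed genes vs their closest exon — and compared with a
two-sided rank-sum test (the comparison is about stochastic ordering, and no
distributional form is assumed). PCR-duplicate removal is exposed as an
off-by-default flag since upstream handling varies.

### Signal profiles

Scale-regions mode: each region body is rescaled into B equal bins (default
B = 60) with fixed-size flank bins (default 50 bp over 5 kb flanks); a bin's
value is the length-weighted mean of the overlapping track runs computed by
exact step-function integration, with uncovered bases contributing zero.
Minus-strand rows are reversed so bin 0 is always 5′. Length-weighting makes
the mean profile of a constant track flat regardless of region-length
heterogeneity (asserted as a mass-conservation test). Bin counts and sizes
are declared defaults, not estimates of any particular published figure;
`max`/`sum` bin statistics sit behind a flag.

### Correlations

L1/host-gene correlation is Pearson's r on normalized linear values across
all samples of a dataset (Spearman available), over pairs given by genic
context calls with the L1 in the expressed set; zero-variance vectors are
flagged and skipped. The summary statistic is the fraction of pairs with
r < 0. `metric_correlation` is a plain Pearson r with two-sided p for
per-sample metrics (e.g. total full-length L1 expression vs number of DE
genes).

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the pipeline assumes, not
sequences or reads:

- **Annotation** — one linear chromosome; non-overlapping gene models with
  2–5 exons (150–1500 bp) and 8–16 kb introns; L1 loci stratified
  intronic/exonic/intergenic (default 65/10/25%), a configurable fraction
  full length (5.5–6.5 kb vs 0.6–3 kb); subfamily-dependent MilliDiv (young
  subfamilies lower), and a baseline-expression weight decreasing with
  MilliDiv so the expressed stratum is younger — the qualitative pattern the
  MilliDiv summary is meant to display.
- **Counts** — negative binomial with variance μ + αμ² (α = 0.05 default,
  a typical bulk RNA-seq dispersion for high-count features), per-feature
  baseline means uniform on [100, 2000] and per-sample size factors uniform
  on [0.7, 1.4]. The default cohort is 9 controls + 9 cases with 3 affected
  cases, mirroring a small postmortem brain cohort; affected cases carry
  8-fold upregulation of 40% of the expressed intronic full-length L1s,
  50 dysregulated genes (half up, half down, 8-fold), and 5 host genes
  negatively coupled (mean halved) to their resident upregulated L1.
  Injected effects target loci with expressed-level baselines, since the
  phenomenon of interest concerns expressed elements. Ground truth is
  written to a sidecar table so downstream checks never re-derive it.
- **Fragments** — uniform mate placement within loci, a configurable
  co-splicing fraction placing mate 2 in a partner locus, and mapq /
  proper-pair contamination knobs.
- **Tracks** — contiguous bedGraph with exact enrichment/background levels
  (run boundaries aligned to region edges) plus optional Gaussian noise.

Not emulated: mappability structure and multi-mapping ambiguity of repeats,
GC/length biases, batch effects, correlated gene–gene structure, spliced
alignments, single-cell data. Passing tests therefore demonstrate the
correctness and calibration of the statistics under their stated model —
they do not show robustness to repeat-mapping artefacts, which in real data
dominate the uncertainty of locus-level TE quantification.

## Numerical and design choices

- Geometric means in log space; medians via numpy.
- Seeds: every generator and resampler takes an explicit seed or
  `numpy.random.Generator`; pipeline runs are byte-reproducible from
  config + seed, and the manifest records both.
- Degenerate inputs are explicit: zero control sd → `undefined` status;
  degenerate resampling null → undefined z with the observed count still
  reported; zero-variance correlation vectors → flagged rows; empty locus
  extraction → undefined sharing pct rather than 0.
- Tie-breaks are deterministic everywhere (closest: smaller start then id;
  host gene: larger overlap then smaller start).
- Boundary readings are literal and unit-tested: "longer than 5 kb" → strict,
  "at least 200 reads" → inclusive, "|z| > 3" → strict, IR thresholds →
  inclusive.

## Problem sizes

Default simulated cohorts use 300 genes and 100 L1 loci on a ~10 Mb
chromosome — large enough for stable size factors and non-trivial context
structure, small enough that the statistical test batteries (20–50 seeded
replicates) and the acceptance script run in seconds. All such sizes are
package defaults, configurable per run.

## Known limitations

- The per-sample z statistic is an outlier screen; its null rate at n = 9
  controls is ≈ 2.2% per feature, and downstream counts (net upregulation,
  DE-gene tallies) inherit that floor. The report's expected-false-positive
  annotation quantifies it but does not remove it.
- Enrichment universes must be the same expressed-gene universe used for the
  z-scores; using a broader universe inflates z.
- The sharing statistic assumes fragment tables already restricted to the
  relevant library (it filters only on proper-pair and mapq), and its
  containment rule makes it sensitive to locus boundary definitions for
  reads near edges.
- `genomic_l1_enrichment` recomputes interval overlaps per draw and is the
  slowest operation at large n; for large annotations prefer the gene-id
  variant.
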