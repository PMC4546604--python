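# Methods

## Scope and model

`teadgrammar` implements the sequence-grammar and target-gene analysis used
to characterize YAP1/TEAD binding from ChIP-seq: YAP1 has no DNA-binding
domain and reaches chromatin through TEAD transcription factors, whose
consensus hexamer is CATTCC (reverse complement GGAATG). The analysis asks
three questions of a peak set: (i) how often peak regions contain the
consensus, relative to a chromosome-shuffle null; (ii) whether homotypic
same-orientation double motifs at particular spacer lengths (3 bp being the
biologically functional configuration) are enriched; and (iii) which genes
the peaks regulate, combining nearest-TSS assignment with
knockdown-expression thresholds, culminating in an expression signature
whose predictive value is measured by a naive-Bayes classifier on tumor
cohorts.

## Coordinate and scanning conventions

All coordinates are 0-based, half-open. The peakzilla peak-table dialect
(1-based starts and summits) is converted on input and restored on output.
Motif statistics are computed on a 151-bp window centred on each peak
summit — the average genomic fragment length — clipped at chromosome ends.

Scanning slides the consensus and its reverse complement across the window
and reports every offset within the mismatch budget (default 1 for the
TEAD hexamer); `N` matches no base. A position matching on both strands
yields two records, preserving strand for pair orientation, but
region-level presence is boolean so double-strand hits cannot inflate
region fractions. Double motifs are all ordered same-strand occurrence
pairs (not only adjacent ones) with a spacer — measured between occurrence
cores in plus-strand coordinates, so minus-strand doubles such as
GGAATG-CAG-GGAATG qualify exactly like CATTCC-TGT-CATTCC — between 0 and
30 bp; overlapping occurrences never pair.

## Null model and enrichment statistics

The null is a chromosome shuffle: each region is relocated uniformly and
independently within its chromosome, preserving width; overlaps among
shuffled regions are allowed and the original location is not excluded.
Enrichment is tested with a one-sided exact hypergeometric upper tail:
the pooled observed and control regions form the population, hit regions
the successes, and the observed set the draw,

  P = sum_{j >= x} C(X, j) C(N - X, n - j) / C(N, n),

evaluated through log-space tail sums (scipy's `hypergeom.logsf`), which
remain finite and accurate for the astronomically small p-values typical of
motif enrichment (log10 p below -300). Per-spacer enrichment is tested the
same way twice: against the shuffled-control spectrum, and against the
pooled (region, spacer) hits at all other spacer lengths within the
observed set. Gene-set enrichment uses the identical tail with the gene
universe as population. P-values are reported raw; Benjamini–Hochberg
adjustment is available but off by default.

## Coverage model

Single-end reads are extended to 150 bp (the average estimated fragment
length) from their 5' end in the read direction — minus-strand fragments
cover [5'−149, 5'] — and each extended fragment adds 10^6/library_size to
every covered base, yielding reads-per-million density. Between-sample
agreement is the Pearson correlation of per-region mean densities;
meta-profiles average density at each offset within ±1,000 bp of the
summit, excluding out-of-bounds positions.

## Target-gene rules

Each peak is assigned to the gene with the nearest TSS on its chromosome
(ties: smallest distance, then lexicographically smallest gene id, for
deterministic output). Distances are summit − TSS, negated for
minus-strand genes so negative always means upstream; peaks within 2 kb of
a TSS are proximal. Feature classification is by summit position with
priority promoter > 5'UTR > exon > intron > intergenic, making the class
fractions mutually exclusive.

Differential expression after knockdown requires, across the four pairwise
knockdown-vs-control comparisons: adjusted p ≤ 1e−5 in all four, a shared
direction, ≥2-fold change in at least one comparison and ≥1.2-fold in the
other three. Fold changes are linear magnitudes with explicit direction;
the DESeq-style adjusted p-values are inputs, not recomputed.
Differential binding requires adjusted p ≤ 1e−5, ≥2-fold enrichment, and
reference-sample density strictly below 100 normalized reads per kilobase.
Boundary semantics are literal: "at least" thresholds are inclusive,
"below" is strict.

## Signature classifier

Samples are labelled by the sum of their expression rank and copy-number
rank (average ranks on ties): extremes mode labels the top and bottom 10%
high/low, all mode splits at the median (ties to low). Boundary and fully
degenerate ties fall back to sample-identifier order, with a warning in
the degenerate case.

The classifier is Gaussian naive Bayes with per-gene, per-class means and
unbiased variances floored at epsilon = 1e−9 × the global training
variance (constant genes therefore cannot produce singular densities);
priors are class frequencies; posteriors are computed in log space.
Expression is log2(x+1)-transformed before fitting by default, which makes
FPKM-like data approximately Gaussian per gene (an untransformed mode
exists). Performance is the mean test AUC — the Mann–Whitney pair
statistic, ties at half weight — over repeated random holdout: each
iteration draws a class-stratified 2/3-train / 1/3-test split (the
stratification guarantees both classes in every fold; plain random splits
could produce single-class test sets), 1,000 iterations by default.
Feature selection ranks genes by absolute standardized mean difference
(pooled SD) and, when used inside cross-validation, runs on the training
fold only so the reduced signature is never chosen on test data.

## Synthetic study conditions

The generators make the whole pipeline testable without genomic downloads.
Their defaults are the study conditions of the motif analysis: 2,500 peaks
(matching the ~2,498-peak SF268 YAP1 set), 151-bp windows, an 86%
single-motif window rate, an 18% same-orientation spacer-3 double rate,
and a 37% hit rate for random control windows (hence a planted fold of
~2.3). Planted rates are *total scanned* rates: the generator computes the
probability that a random window of the background composition already
contains an incidental consensus match (a Poisson-binomial per-offset
match probability, assumed independent across offsets) and solves for the
planting probabilities — per-peak singles, per-peak doubles, and a
genome-wide background motif density — that bring the scanned totals to
the targets. Planted motif bases are written after the background so they
are never mutated; the planting ledger records every planted site so tests
can separate planted from incidental occurrences.

The synthetic conditions use exact-match scanning (max_mismatch = 0).
With a 1-mismatch budget, a uniform-composition 151-bp window already has
a ~74% incidental hit probability, which no planting scheme can reconcile
with an 86%/37% observed/control contrast; the mismatch machinery itself
is verified against exhaustive enumeration oracles instead. Enrichment
runs place the 2,500 peaks on a 60-Mb genome (4 × 15 Mb) so that shuffled
control windows rarely intersect true peaks (peak footprint 0.63%); the
residual inflation of the control rate is within the binomial noise at
n = 2,500.

Read libraries are mixtures of a uniform background and per-peak Gaussian
components (fragment centres Normal(summit, fragment_length/2)),
strand-balanced, with reads apportioned among peaks proportionally to peak
score — replicate libraries therefore agree on which peaks are strong, as
real replicates do, giving replicate region-density correlations near 0.9
at the default library sizes. Expression matrices are log-normal per gene
with signature genes shifted by `effect_size` (in units of the per-gene
log2 noise SD) in high-activity samples; the default effect size of 1 SD
per signature gene is a moderate, realistic choice (the classifier
separates such cohorts almost perfectly, as expected for a 70-gene
signature with independent per-gene shifts).

What the synthetic data does not emulate: genomic sequence composition
bias and repeats, chromatin-driven clustering of binding sites, correlated
gene-gene expression structure, and cohort-level confounders. Passing the
recovery suites therefore demonstrates correctness of the statistical
machinery under its stated model, not field performance on real tumors —
on real data the signature AUC is bounded by biological noise (published
values for comparable signatures are ~0.8), while the synthetic default
reaches ~1.0 by construction.

## Numerical choices and problem sizes

Hypergeometric tails: log-space, exact; comparisons in tests at 1e−10
relative tolerance. Variance floor: 1e−9 × global variance. AUC ties:
half weight via average ranks. Shuffle and holdout randomness: numpy
`default_rng`, fully seed-deterministic; child seeds are drawn below 2^31.
Test-suite simulations use 2,500-peak genomes on 24–60 Mb for motif
recovery (10 seeds), 200 holdout iterations for the classifier null, and
10,000-sequence oracle sweeps for scanning — sizes chosen to keep the
whole suite in tens of seconds while leaving binomial confidence intervals
tight enough to detect calibration errors of a few percent.

## Known limitations

- The exact region-definition strategy behind published overlap figures is
  not reproducible from text descriptions alone; `overlap_fraction` uses
  ≥1 bp intersection of the reported intervals with the threshold exposed.
- Degenerate-consensus tables (IUPAC-style motif preference lists) are out
  of scope; only exact-consensus-with-k-mismatches scanning is provided.
- GTF parsing is not implemented; annotations enter as four-column TSV
  (chrom, start, end, class) and TSS tables as TSV.
- The incidental-match calibration treats window offsets as independent;
  clumping of overlapping matches biases planted rates by well under the
  binomial noise at the default problem sizes.
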