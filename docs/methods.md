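# Methods

This note documents the models and numerical choices behind `sertoli-sig`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the method left room.

## Normalization

**CPM.** counts / library size × 10⁶, with library sizes defaulting to
column sums (pre-filter totals are accepted; they only have to be
positive). The expression filter keeps genes strictly above 0.4 CPM in at
least 2 complete-spermatogenesis (CS) libraries — strict inequality at the
threshold, so a gene at exactly 0.4 CPM everywhere is removed. When a
per-gene biotype annotation is supplied, non-mRNA biotypes (anything
outside `protein_coding`) are purged before filtering; without annotation
the purge is a no-op, since no authoritative purge list exists for an
arbitrary user gene universe.

**TMM.** Scaling factors follow the trimmed-mean-of-M-values recipe: for
each sample against a reference (the sample whose upper-quartile CPM is
closest to the cohort mean, unless overridden), per-gene log-ratios M and
log-abundances A are computed over co-expressed genes, the M distribution
is trimmed 30% per tail and A 5% per tail, and the surviving M-values are
combined with inverse-asymptotic-variance weights. Factors are renormalized
to geometric mean 1. The trim fractions are the published defaults of the
method and are exposed as arguments. During development the implementation
was checked against edgeR's `calcNormFactors` on a 300 × 4 fixture
(agreement to 1e-7); the shipped tests use an independently coded
brute-force oracle instead so the suite has no R dependency.

**log2 transform** uses a prior count of 1.0 (config `log_prior`); the
choice only matters for near-zero CPMs and is stated rather than hidden.

**Actin ratios.** CPM divided by the beta actin CPM of the same sample
(`ACTB` by default, overridable). This is the appropriate scale when
overall cellularity differs between groups: somatic transcripts — beta
actin included — are globally enriched ~3-fold in germ-cell-depleted
testes, and the ratio removes that shared factor. ACTB absent or zero in
any sample is a hard error.

**Median rescaling of the signature panel.** Each sample's signature CPMs
are multiplied by target/sample-median, the target being the median of
per-sample medians. This removes the residual global shift between CS and
SCO before the panel is re-tested, so the re-test sees relative changes
within the panel. The operation is idempotent and refuses samples with a
zero panel median.

## Differential testing

**Conditional NB exact test.** Counts are first equalized to a common
effective library size (geometric mean of TMM-corrected sizes, rounding
half-to-even) so the group totals are exchangeable. Per-sample counts are
modelled NB with variance μ + φμ²; group sums are then NB with sizes
rᵢ = nᵢ/φ, and conditioning on the total T gives the Pólya law

    P(S₁ = s | T) ∝ C(s + r₁ − 1, s) · C(T − s + r₂ − 1, T − s),

normalized in closed form by C(T + r₁ + r₂ − 1, T) (the NB convolution
identity), which keeps the computation a single vectorized pass over the
support. At φ = 0 the law is Binomial(T, n₁/(n₁+n₂)) and the p-value
equals the exact binomial test's. Two-sided p-values sum the probabilities
of all splits no more probable than the observed one, with a 1e-7 relative
tolerance so floating-point ties count as ties; T = 0 gives p = 1 by
convention. The full support is enumerated — at the default 17M-read depth
(T ≈ 2×10⁵) this is ~10⁸ cheap vector operations for a 1,000-gene run,
a few tens of seconds at most and exact rather than approximated.

**Dispersion.** Per-gene method-of-moments on the equalized counts: pooled
within-group variance s², grand mean μ, raw φ = max(0, (s² − μ)/μ²), then
shrunk halfway toward the cohort median (all-zero genes get φ = 0). This
is a deliberately simple stabilizer, not a reimplementation of
empirical-Bayes tagwise shrinkage; its properties (Poisson data give
median φ ≤ 0.05; the exact test stays calibrated under the null) are what
the tests assert. The null calibration test runs the exact test at the
generating dispersion to isolate the test's own calibration from estimator
noise.

**BH FDR** is the Benjamini–Hochberg step-up as implemented in statsmodels,
validated in tests against a literal step-up oracle. Significance is
strict (FDR < 0.05) for count tests and inclusive (p ≤ 0.005) for the
actin-ratio t-tests, matching the stated conventions of each comparison.

**t-tests** are Welch by default (a config switch selects pooled-variance
Student); with only "two-tailed t-tests" specified, the unequal-variance
form is the safer default for a 4-vs-7 design with different cellularity.
Zero-variance degenerate genes get t = 0, p = 1 when the means agree and
p = 0 otherwise.

## The signature screen

Criterion (a) is a share of the testis total (Sertoli fraction ≥ 0.6,
inclusive). Criteria (b) and (c) compare *per-cell* expression levels: the
subtraction estimate divided by the Sertoli mRNA fraction against the
per-cell reference columns — ≥ 2× Leydig (inclusive) and strictly greater
than every germ type. This per-cell reading of (b)/(c) is interpretive:
"expression by Sertoli cells twice that of Leydig cells" is a statement
about cells, not about bulk shares, and the per-cell scale is the one on
which the two sides are commensurable.

Numerical choices: reference columns are rescaled to sum 10⁶ before
mixing, making composition fractions interpretable as mRNA-mass fractions
and putting per-cell columns on the bulk-CPM scale (the exact
cross-platform harmonization used for the original published panels is not
reproducible here; the rescaling rule is this package's documented
stand-in). Negative subtraction results are floored at zero so fractions
live in [0, 1]. Per-cell mRNA content defaults to 1 for every cell type,
overridable. Candidates absent from the human reference (e.g. manually
augmented transcripts not measured on the source arrays) are treated as
zero non-Sertoli contribution and flagged `in_reference=False`; they pass
(b)/(c) vacuously, which mirrors how undetected-on-array transcripts must
be handled and is visible in the output flags.

Ortholog mapping admits only one-to-one pairs; unmapped and multi-mapped
candidates are listed with reasons in `mapping_report.tsv` rather than
silently dropped.

## Exploratory views

K-means runs on row-z-scored log2 expression (clusters should group
expression *profiles*, not absolute abundance; constant rows map to the
zero profile), k-means++ with 50 restarts and a fixed seed. The distance
metric and preprocessing of the original clustering are unstated, so this
choice is the package's own. PCA centers genes across samples, orders
components by explained variance and fixes signs by making each
component's largest-magnitude loading positive, so scores are reproducible
across SVD implementations.

## Cohort arithmetic

Group means are computed over non-missing values only (FSH means skip
donors with no measurement), rounded half-up: age and weight to 1 decimal,
FSH to 2. Egg and embryo means are reported both raw and rounded to the
nearest integer, because clinical tables conventionally print small-group
means with decimals and larger-group means as integers; nearest-integer
half-up reproduces both conventions from the same raw means. Height
strings (feet'inches") are parsed but excluded from means — a modal height
string is not an arithmetic mean.

## The synthetic cohort

**What it emulates.** Per-cell-type expression panels for rat (Sertoli,
Leydig, spermatogonia, pachytene spermatocytes, round spermatids) and
human (the same minus Sertoli, which is withheld from the pipeline exactly
as no human Sertoli transcriptome was available to the original analysis);
a CS composition dominated by germ cells (Sertoli 0.15, Leydig 0.10, germ
0.75) and an SCO composition with germ cells depleted to 0.10 total and
somatic fractions enriched ~3.6-fold (Sertoli 0.55, Leydig 0.35); bulk
libraries of 17M reads, 4 CS + 7 SCO, NB counts with φ = 0.1 around the
composition-weighted mixture; and 50 designated signature genes among
1,000 (default sizes; both scale up).

**Planted structure.** Baselines are log-normal(meanlog 1, sdlog 1.2) per
gene, shared across cell types, with mild per-(gene, cell-type)
log-normal(0, 0.2) jitter per panel. Signature genes are Sertoli-specific
the way real marker genes are — their *non-Sertoli* columns are depleted
to sertoli/ratio with one binding cell type, so the realized
Sertoli-vs-max-other ratio equals the drawn per-gene factor exactly.
Factors are uniform on [12, 24]: the floor of 12 guarantees a noiseless
Sertoli fraction of at least 0.15·12/(0.15·12 + 0.85) ≈ 0.68 under the CS
composition, comfortably above the 0.6 criterion (an 8-fold floor, for
comparison, caps the noiseless fraction at 0.585 and cannot satisfy the
criterion at all). Depletion rather than Sertoli inflation is essential:
with 5% of genes enriched ~18-fold, inflating the Sertoli column would
nearly double its mass and the per-column rescaling would erode the
planted ratio by that same factor. Near-miss decoys (5% of genes) carry a
realized ratio of exactly 3.5 and always fail the 4-fold screen; a
configurable fraction of ortholog rows is unmapped or multi-mapped to
exercise the mapping report. ACTB is planted as an abundant, uniformly
expressed housekeeping gene so actin normalization runs on synthetic
cohorts. In the SCO group, random subsets of the signature (25% down at
0.2×, 30% up at 2.5×) have aberrant Sertoli per-cell expression — the
deficit pattern the median-rescaled re-test is built to detect.

**What it does not emulate.** Read-level artifacts (mapping bias, GC
effects), batch effects, gene-length differences, within-group composition
variability, and correlated gene modules. Passing recovery tests therefore
demonstrates the correctness of the screen's arithmetic and decision
rules under the stated noise model — not robustness to real-data artifacts
upstream of the count matrix.

**Problem sizes.** Tests and the acceptance script run the default
1,000-gene cohort and a 10,000-gene null simulation; these sizes make the
conditional enumeration and the end-to-end screen complete in seconds
while leaving every statistical check adequately powered.

## Known limitations

- The subtraction deconvolution inherits the quality of the reference
  panels and the composition table; composition is an input, never
  estimated from the data.
- Dispersion shrinkage is a fixed-weight moment estimator; genuinely
  heavy-tailed dispersion distributions would favor empirical-Bayes
  alternatives.
- The signature criteria are threshold rules; no uncertainty is propagated
  into the pass/fail flags.
- Real cohort sizes (4 vs 7) give the exact test limited power; the
  whole-transcriptome significant-gene counts on synthetic data are
  correspondingly conservative.
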