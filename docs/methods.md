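# Methods

## Coordinate conventions

All footprint operations work on a non-redundant, transcript-space
reference: one transcript per gene (the longest isoform; ties break to
the lexicographically smallest transcript id), laid out as
5′UTR | CDS | 3′UTR in 0-based half-open coordinates. The CDS occupies
`[utr5_len, utr5_len + cds_len)` and its length is a multiple of 3. A
read is represented solely by its 5′-most aligned nucleotide; no P-site
offset is applied, favoring fidelity to the convention over
sophistication. The stop-codon anchor for metagene profiles is the first
nucleotide of the last CDS codon (`utr5_len + cds_len − 3`); the last
three CDS nucleotides are treated as the stop codon. This convention is
a package choice (start/stop anchoring conventions differ across tools)
and is pinned by tests.

## Footprint QC

* **Length distribution** — a histogram of read lengths; counts sum to
  the number of input alignments (conservation is tested).
* **Triplet periodicity** — frame of a read is
  `(five_prime_pos − utr5_len) mod 3`; only 5′ ends inside the CDS are
  assigned. UTR-landing reads appear in the length histogram but not in
  periodicity. Fractions are reported per read length and sum to 1.
* **Metagene profiles** — transcripts qualify with ≥ 256 aligned
  footprints (inclusive threshold) and a nonzero annotated 5′UTR and
  3′UTR. Per-offset 5′-end counts over ±100 nt (configurable) around
  the anchor are averaged over the transcripts *covering* that offset
  and divided by the library's total mapped reads. Offsets no qualifying
  transcript covers are reported as missing (NaN), never zero — the
  averaging behavior beyond short UTRs is otherwise ill-defined. The
  profile is invariant to uniform depth scaling, and a single-transcript
  profile with T in-window reads sums to T / total_mapped.
* **Density tracks** — per-position 5′-end counts divided by the
  replicate's library size, averaged across replicates.

## Counting rules

CDS counting increments a gene iff the footprint 5′ end lies in
`[utr5_len + 45, utr5_len + cds_len − 15)`, i.e. excluding the first 15
and last 5 codons where initiating/terminating ribosomes pile up.
"Aligned to the first 15 codons" is read as "5′ end falls within those
codons", consistent with the 5′-end representation used everywhere else.
Exonic counting (mRNA-type libraries) counts any read with a 5′ end on
the transcript. Reads on unannotated transcripts are dropped and logged.
The coverage filter retains a gene iff it has ≥ `min_reads` (default 10,
inclusive) in every sample of both the primary assay and its matched
mRNA.

## Normalization

Median-of-ratios size factors: over genes with nonzero counts in every
sample, `s_j = median_g(K_gj / geometric_mean_g(K_g·))`; normalized
counts are `K_gj / s_j`. Matrices with no all-nonzero gene raise an
error pointing at the coverage filter. Note two consequences exercised
by the tests: size factors are invariant to scaling *all* samples
jointly (only relative depth matters), and strongly asymmetric
differential expression shifts the median and biases fold changes — the
usual composition-bias caveat of this normalization.

## Differential expression (NB Wald stand-in)

The test is a stand-in for the external DE tools used in this field;
its acceptance surface is distributional (type-I error, FDR control,
effect recovery), not numeric identity with any specific tool.

Per gene, `log2fc = log2((m̄_mut + c)/(m̄_wt + c))` on normalized
condition means with pseudocount c = 0.5 (configurable; applied wherever
a log or ratio is taken). The Wald SE comes from the delta method under
NB moments `Var(K) = μ + αμ²`:
`Var(log2 m̄_c) = (m̄_c + α m̄_c²) / (n_c (m̄_c + c)² ln²2)`. Two-sided
normal p-values, BH-corrected; the default significance threshold is
FDR < 0.1, matching the study design this package targets.

**Dispersion estimation.** The raw per-gene estimate pools
within-condition moments,
`α̂ = Σ_c (n_c−1)(s²_c − m̄_c) / Σ_c (n_c−1) m̄_c²`. A trend is fitted by
averaging the (unbiased) moment estimates within ~20 expression bins and
passing a Theil–Sen line through the bin means in log–log space —
binwise *means* rather than medians because the MoM estimator at 4 df is
heavily skewed and conditioning on positivity would bias a median fit.
By default the per-gene estimate is then moderated adaptively: the ratio
of the pooled gene variance to the trend-implied NB variance is shrunk
toward its empirical-Bayes prior (prior df estimated from the spread of
log variance ratios via the digamma/trigamma moment equations). A fixed
linear blend `w·max(α̂,0) + (1−w)·α_trend` is available via
`shrinkage_weight=w`. The adaptive default exists because a fixed
half-and-half blend of a 4-df moment estimate leaves the Wald test
anticonservative (measured empirical type-I ≈ 0.075 at nominal 0.05
under a homogeneous NB null at 3 vs 3); with adaptive moderation the
measured type-I is 0.049–0.063 over independent null simulations.

**Consistency sets.** A gene is "consistently up" iff FDR < 0.1 and
log2fc > 0 in *every* supplied mRNA dataset (symmetrically for down);
the sets are disjoint by construction.

## Differential translation efficiency

TE is `TE_gj = (rpf_norm + c)/(mrna_norm + c)` per positionally paired
replicate (each assay normalized separately; RPF and mRNA replicates are
paired by sorted sample id within condition — the design is assumed
matched). The test statistic is `Δ = mean(log TE)_mut − mean(log TE)_wt`
with `z = Δ / SE` and a two-sided normal p, BH-corrected;
`log2_te_ratio = Δ / ln 2`.

`SE² = max(moderated replicate variance, counting floor)`. The pooled
replicate variance of log TE (df = n_wt + n_mut − 2) is moderated across
genes exactly as in limma-style empirical Bayes: a scaled inverse-χ²
prior (d₀, s₀²) is fitted by matching the mean and excess variance of
log s² (digamma/trigamma equations; trigamma inverted by bisection), and
the posterior variance `(d₀s₀² + df·s²)/(d₀ + df)` replaces s². The
counting floor `Σ_j [1/(K_rpf,j + c) + 1/(K_mrna,j + c)] / n_c²` (raw
counts, summed within each condition) bounds the variance from below by
the Poisson noise of the counts themselves, protecting low-coverage
genes whose replicate variance is accidentally tiny. The moderation is
what makes a *normal* reference defensible at 3 vs 3: with homogeneous
gene variances the fitted prior df diverges and the test is exactly
calibrated (measured type-I 0.041–0.059 at nominal 0.05); with strongly
heterogeneous variances the normal p is mildly anticonservative for
high-variance genes — a documented limitation of the z-test formulation.

Genes must be pre-filtered with the coverage filter; a gene with zero
counts across every sample of an assay raises an error naming the fix.

## Protein differential test

Two-tailed two-sample Student t-test per gene on log2 normalized
spectral abundances; no multiple-testing correction — significance is
the raw p < 0.01, the convention for this proteomics layer. Zero
variance in both groups with equal means yields p = 1; zero variance
with unequal means applies a variance floor (1e−8, logged) so the
statistic stays finite.

## Concordance classification

For each protein with p < 0.01: mRNA evidence is a significant
(FDR < 0.1) change in ≥ 1 mRNA dataset (configurable to "all") whose
log2fc sign equals the protein's; TE evidence is the union over the TE
result tables (footprinting-based and/or polysome-based). Categories —
`both`, `mrna_only`, `te_only`, `unexplained` — partition the
significant-protein set. Sign agreement is required by default because
"consistent" support should not count an mRNA decrease as explaining a
protein increase; `require_sign=False` disables it. A gene missing from
a result table contributes no evidence.

## Regression, correlation, PCA

`explain_variance` is OLS with intercept of protein log2fc on the chosen
predictor columns; collinear columns are dropped (earliest kept) with a
warning. AIC uses the Gaussian likelihood with
k = n_slopes + intercept + residual variance, stated so values are
comparable across implementations. `fold_change_correlation` is Pearson
r with pairwise deletion of missing genes; zero variance returns NaN
with a warning. `sample_pca` runs PCA on log2(normalized + 1),
gene-centered, returning per-sample coordinates and variance-explained
fractions.

## Isotope natural-abundance correction

The correction matrix for a fragment with n tracer carbons: column k is
the convolution of (i) the binomial natural-¹³C distribution over the
n − k unlabeled carbons and (ii) the natural mass-isotope distributions
of all non-tracer atoms (IUPAC representative compositions; ¹³C 0.0107,
²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205; S, P, Si also
tabulated), shifted by k and truncated to the measured masses M+0..M+n.
By default the truncation deficit is left in place (columns sum to ≤ 1);
`renormalize_columns=True` rescales columns to 1 — both conventions are
flag-selectable because reported MDVs in the literature follow either.
Correction solves `M x = observed` by NNLS and renormalizes x to sum
to 1, so measurement noise can never produce negative isotopologue
fractions (the reason NNLS is used instead of matrix inversion).
Summaries: fractional contribution `Σ i·mᵢ / n` (linear in the MDV,
invariant to renormalization) and total labeled `Σ_{i≥1} mᵢ`. Both
require a corrected MDV.

## Synthetic-data generator

The generator emulates the structure of a replicated two-condition
translatome study: 3 WT vs 3 mutant clones per assay, ~10⁴ genes,
footprints of 30–33 nt with 3-nt periodicity, and planted effects at the
study's scale — defaults of 368/421 transcriptionally up/down genes with
|log2FC| uniform on [1, 2.5], 67 TE-changed genes at |log2FC| =
log2(2.5), protein changes for 116 of the mRNA-changed genes plus 129
genes with purely post-translational changes, and one marker gene
carrying concordant upregulation at every layer (mRNA FC 3.8, TE FC 2.5,
protein FC 4.7) whose mean expression is pinned one sigma above the
median so the pattern is detectable at realistic depth.

Counts are Gamma–Poisson: `K ~ Poisson(Gamma(1/α, αμ))`, giving
`Var = μ + αμ²` exactly, with Poisson at α = 0. The mRNA mean carries
only the transcriptional effect; the RPF mean multiplies in the TE
effect; the polysomal matrix is an independent RPF-like realization.
Gene mean expression is log-normal (median 150 counts, σ = 1.2 in log
space — a right-skewed abundance distribution typical of bulk assays);
per-sample library depth defaults to 5×10⁶ assigned footprints for read-
level simulation (a typical deposited library size; configurable).
Protein abundances are log2-normal around log2(mean expression + 1) with
replicate noise σ = 0.3 by default.

Footprint 5′ ends sit on a uniformly chosen codon with frame-0
probability `frame0_prob` (frames 1 and 2 equiprobable otherwise);
`placement="uniform"` instead draws 5′ ends uniformly over the
transcript, emulating the frame-agnostic behavior of mRNA-seq reads.
Footprints are simulated directly in transcript coordinates — genomic
simulation, spliced alignment, sequence content, adapters and rRNA
contamination are all out of scope, so passing tests say nothing about
alignment artifacts, mapping bias, or UTR-overlapping footprint
chemistry in real libraries. Counts are drawn independently per gene, so
correlated expression programs and batch effects are also not modeled.

**Seeding.** Seeds are mandatory. A master seed streams per-component
sub-seeds via `numpy.random.SeedSequence([seed, stream_id])` with a
fixed stream id per output (annotation=1, truth=2, footprints=3,
mrna=4, rpf=5, polysomal=6, proteins=7, mdv=8), so each stage is
independently reproducible and byte-identical given the same
configuration.

## Problem sizes and numerical choices

The test suite and the acceptance script use simulation sizes chosen as
the smallest designs at which the distributional claims are sharp:
50,000 footprints for frame recovery (binomial SE ≈ 0.0016), 2,000-gene
nulls for type-I calibration, 2,000 genes with 100 planted effects for
TE recovery, a 3,000-gene multi-omics design for classifier accuracy,
200 replicates of n = 246 for the regression sampling distribution, and
100 random labeling vectors over C2–C6 fragments for the isotope round
trip. Tolerances follow the sampling theory of each check (e.g. ±0.01 on
a 50k-read binomial fraction; 1e−6 on NNLS round trips; 1e−10 against
the closed-form OLS oracle). Ties, degenerate inputs and zero-variance
cases are resolved explicitly: inclusive thresholds (≥ 256 footprints,
≥ 10 reads), lexicographic isoform tie-break, p = 1 for exactly equal
groups, NaN (with warning) for undefined correlations, and errors that
name the offending gene/transcript/sample.

## Known limitations

* The DE/TE tests are calibrated stand-ins, not reimplementations of any
  external tool; numeric agreement with those tools is out of scope.
* Normal (rather than t) reference for the TE z-test relies on variance
  moderation; with few genes (< ~50) the prior fit is weak and p-values
  degrade toward the unmoderated z-test.
* Median-of-ratios normalization assumes most genes unchanged; strongly
  asymmetric regulation biases fold changes (composition bias).
* Multi-mapping, fractional assignment and genomic BAM projection are
  not implemented; input alignments are assumed transcript-space and
  pre-filtered.
* The isotope matrix assumes a single tracer element and natural
  abundance for all unlabeled positions; tracer impurity correction is
  not modeled.
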