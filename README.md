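# translatome

A tested, reusable pipeline for translatome analysis: ribosome-footprint
quality control, CDS/exon counting on a non-redundant transcriptome,
differential expression and differential translation efficiency,
multi-omics concordance classification of protein changes, and ¹³C
isotopologue natural-abundance correction. It is aimed at computational
biologists who integrate ribosome footprinting (RPF-seq), mRNA-seq,
polysomal RNA-seq and quantitative proteomics from a replicated
two-condition design (e.g. isogenic wild-type vs mutant clones, 3 vs 3),
and at method developers who need a synthetic-data generator with planted
ground truth to validate such pipelines end to end.

## What it computes

**Footprint QC.** Reads are represented by their 5′-most aligned
nucleotide in transcript coordinates. The package reports the footprint
length distribution, the triplet periodicity per read length (frame of a
read = (pos − ℓ₅′UTR) mod 3 for 5′ ends inside the CDS), metagene
profiles of footprint density around start/stop codons (transcripts with
≥ 256 footprints and annotated UTRs, ±100 nt, normalized by mapped
library size), and per-gene density tracks averaged over replicates.

**Counting.** The annotation is reduced to the longest isoform per gene.
Footprints are counted for a gene when the 5′ end falls within the CDS,
excluding the first 15 and last 5 codons where ribosomes accumulate;
mRNA-type reads are counted anywhere on the transcript. Genes with
< 10 reads in any sample of either assay are filtered out before TE
testing.

**Differential expression.** Counts are normalized with median-of-ratios
size factors. For each gene the NB Wald statistic is

  log₂FC = log₂((m̄ᵐᵘᵗ + c)/(m̄ʷᵗ + c)),  z = log₂FC / SE,

with the delta-method SE under Var(K) = μ + αμ², where the per-gene
dispersion α is moderated toward a robust mean–dispersion trend, and
Benjamini–Hochberg correction across genes (FDR < 0.1 by default).
Genes consistently significant in all mRNA datasets form the up/down
consistency sets.

**Translation efficiency.** TE = RPF/mRNA per replicate (size-factor
normalized, pseudocount c = 0.5); the TE change is TE(mut)/TE(wt). The
differential-TE z-test compares mean log TE between conditions with an
empirical-Bayes moderated replicate variance floored by Poisson counting
noise, two-sided normal p, BH-corrected.

**Integration.** Protein changes (two-tailed t-test on log₂ normalized
spectra, p < 0.01) are classified as `mrna_only`, `te_only`, `both`, or
`unexplained` by sign-concordant significant support in the mRNA and TE
layers; OLS regression quantifies the protein variance the other layers
explain (R², Gaussian AIC), plus fold-change Pearson correlations and
sample-level PCA.

**Isotope correction.** For a fragment with n tracer carbons, the
correction matrix column k is the binomial ¹³C distribution over the
n−k unlabeled carbons convolved with the natural mass-isotope
distributions of all other atoms, shifted by k and truncated to
M+0..M+n. Observed mass-distribution vectors are corrected by
nonnegative least squares and summarized as fractional contribution
Σᵢ i·mᵢ / n.

**Synthetic data.** `simulate_*` functions generate annotations,
footprints (30–33 nt, 3-nt periodicity), NB count matrices, protein
tables and MDVs with planted transcriptional/TE/protein effects and a
mandatory seed, so every downstream claim is checkable against ground
truth.

## Worked example

```python
import numpy as np, translatome as tl

config = tl.SimulationConfig(seed=20, n_genes=2000, nb_dispersion=0.01)
truth = tl.simulate_truth(config, n_mrna_up=80, n_mrna_down=80, n_te=40,
                          n_protein_from_mrna=40, n_protein_unexplained=40,
                          mean_log=float(np.log(500.0)))
mrna, rpf, poly = tl.simulate_counts(truth, config)
proteins = tl.simulate_proteins(truth, noise_sd=0.3, config=config)

de = tl.differential_expression(mrna)
kept = tl.filter_low_coverage(rpf, mrna, min_reads=10)
te = tl.differential_te(rpf.subset_genes(kept), mrna.subset_genes(kept))
pdiff = tl.protein_differential(proteins)
records, summary = tl.classify_protein_changes(pdiff, {"mrna": de}, {"rpf": te})

print("DE genes at FDR<0.1:", int((de.fdr < 0.1).sum()))
print("TE changes at FDR<0.1:", int((te.fdr < 0.1).sum()))
print("significant proteins (p<0.01):", summary.n_total)
print("category percentages:", {k: round(v, 1) for k, v in summary.percentages.items()})
print("marker gene:", records.loc[tl.MARKER_GENE, "category"],
      "| TE log2 ratio:", round(float(te.loc[tl.MARKER_GENE, "log2_te_ratio"]), 2))
```

prints

```
DE genes at FDR<0.1: 183
TE changes at FDR<0.1: 46
significant proteins (p<0.01): 90
category percentages: {'both': 1.1, 'mrna_only': 38.9, 'te_only': 0.0, 'unexplained': 60.0}
marker gene: both | TE log2 ratio: 1.16
```

Of the 160 planted mRNA effects, 183 genes reach FDR < 0.1 (the planted
ones plus a small FDR-controlled tail); all 41 planted TE changes that
survive the coverage filter (40 + the marker) are among the 46 TE calls.
Among the 90
detectable protein changes, ~39% are explained by transcription alone,
one gene (the planted marker, which carries concordant mRNA, TE and
protein upregulation) is explained by `both`, and the rest are
`unexplained` — the planted post-translational changes. The marker's
estimated log₂ TE ratio of 1.16 recovers the planted 2.5-fold change
(log₂ 2.5 ≈ 1.32) within sampling error.

A CLI mirrors the library (`translatome simulate|qc|count|diff-expr|
diff-te|integrate|isocorrect`); see `translatome --help`.

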