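"""Synthetic translatome data with planted ground truth.

Emulates the structure of a 3 WT vs 3 R98S-mutant replicate design over
~10^4 genes: a transcript-space annotation, ribosome footprints of
30-33 nt with 3-nt periodicity, negative-binomially distributed mRNA /
footprint / polysomal count matrices carrying planted transcriptional
and translation-efficiency effects, log-normal protein abundances, and
13C mass-distribution vectors convolved with natural isotope abundance.

Seeds are mandatory.  One master seed streams per-component sub-seeds
through ``numpy.random.SeedSequence([seed, stream])`` with a fixed
stream id per output (annotation, truth, each assay, ...), so each stage
is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation import Annotation, TranscriptAnnotation
from .containers import CountMatrix, ProteinTable
from .counting import ALIGNMENT_COLUMNS
from .isotope import MDV, build_correction_matrix, parse_formula

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "simulate_annotation",
    "simulate_truth",
    "simulate_footprints",
    "simulate_counts",
    "simulate_proteins",
    "simulate_mdv",
    "MARKER_GENE",
]

# Fixed sub-seed stream ids (see module docstring).
STREAMS = {
    "annotation": 1,
    "truth": 2,
    "footprints": 3,
    "mrna": 4,
    "rpf": 5,
    "polysomal": 6,
    "proteins": 7,
    "mdv": 8,
}

#: The planted marker gene carrying the "concordant everywhere" pattern:
#: transcriptional, TE and protein upregulation all significant (the
#: phosphoserine-phosphatase-like behaviour).
MARKER_GENE = "gene_psph_like"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    ``nb_dispersion`` is the negative-binomial overdispersion alpha in
    Var = mu + alpha*mu^2 (alpha = 0 falls back to Poisson);
    ``frame0_prob`` is the probability that a footprint 5' end lands in
    frame 0 of the CDS, frames 1 and 2 being equiprobable otherwise.
    """

    seed: int
    n_genes: int = 10_000
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    frame0_prob: float = 0.85
    read_length_range: tuple[int, int] = (30, 33)
    utr5_range: tuple[int, int] = (30, 300)
    cds_range: tuple[int, int] = (300, 3000)
    utr3_range: tuple[int, int] = (60, 600)
    library_size: int = 5_000_000
    conditions: tuple[str, str] = ("WT", "R98S")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if not (1.0 / 3.0 <= self.frame0_prob <= 1.0):
            raise ConfigurationError("frame0_prob must lie in [1/3, 1]")
        for name in ("read_length_range", "utr5_range", "cds_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} > max {hi}")
            if lo < 0:
                raise ConfigurationError(f"{name}: lengths must be >= 0")
        if self.cds_range[1] < 3:
            raise ConfigurationError("cds_range must allow at least one codon")
        if self.library_size < 1:
            raise ConfigurationError("library_size must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Sub-seeded generator for one named output stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, STREAMS[stream]]))


def _gene_ids(n: int, plant_marker: bool = True) -> list[str]:
    width = max(5, len(str(n)))
    ids = [f"gene_{i + 1:0{width}d}" for i in range(n)]
    if plant_marker and n:
        ids[0] = MARKER_GENE
    return ids


def simulate_annotation(config: SimulationConfig, plant_marker: bool = True) -> Annotation:
    """One transcript per gene with lengths drawn from the configured
    ranges; CDS lengths are multiples of 3.  Deterministic given the seed.

    ``plant_marker`` keeps the gene universe aligned with
    :func:`simulate_truth`, which names its first gene ``MARKER_GENE``.
    """
    rng = config.rng("annotation")
    n = config.n_genes
    utr5 = rng.integers(config.utr5_range[0], config.utr5_range[1] + 1, size=n)
    min_codons = max(1, -(-config.cds_range[0] // 3))  # ceil
    max_codons = config.cds_range[1] // 3
    if min_codons > max_codons:
        raise ConfigurationError(
            f"cds_range {config.cds_range} contains no multiple of 3"
        )
    cds = 3 * rng.integers(min_codons, max_codons + 1, size=n)
    utr3 = rng.integers(config.utr3_range[0], config.utr3_range[1] + 1, size=n)
    return Annotation(
        TranscriptAnnotation(
            transcript_id=f"{gene}.t1",
            gene_id=gene,
            utr5_len=int(utr5[i]),
            cds_len=int(cds[i]),
            utr3_len=int(utr3[i]),
        )
        for i, gene in enumerate(_gene_ids(n, plant_marker))
    )


def simulate_truth(
    config: SimulationConfig,
    n_mrna_up: int = 368,
    n_mrna_down: int = 421,
    n_te: int = 67,
    n_protein_from_mrna: int = 116,
    n_protein_unexplained: int = 129,
    mrna_log2fc_range: tuple[float, float] = (1.0, 2.5),
    te_log2fc: float = float(np.log2(2.5)),
    unexplained_log2fc_range: tuple[float, float] = (1.0, 2.5),
    mean_log: float = float(np.log(150.0)),
    mean_sigma: float = 1.2,
    plant_marker: bool = True,
) -> pd.DataFrame:
    """Planted per-gene effects mirroring the study's scale.

    Defaults: 368 transcriptionally up / 421 down genes, 67 genes with a
    TE change of magnitude log2(2.5), protein changes for 116 of the
    mRNA-changed genes plus 129 genes with no mRNA/TE support, and one
    marker gene (``MARKER_GENE``) upregulated at every layer
    (mRNA log2fc = log2(3.8), TE log2fc = log2(2.5), protein
    log2fc = log2(4.7)).  Returns a table with true_mrna_log2fc,
    true_te_log2fc, true_protein_log2fc, mean_expression and the
    generative category ('both', 'mrna_only', 'te_only', 'unexplained',
    'null') of each gene.
    """
    needed = n_mrna_up + n_mrna_down + n_te + n_protein_unexplained + int(plant_marker)
    if needed > config.n_genes:
        raise ConfigurationError(
            f"planted effects need {needed} genes but n_genes={config.n_genes}"
        )
    if n_protein_from_mrna > n_mrna_up + n_mrna_down:
        raise ConfigurationError(
            "n_protein_from_mrna exceeds the number of mRNA-changed genes"
        )
    rng = config.rng("truth")
    genes = _gene_ids(config.n_genes, plant_marker)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_mrna_log2fc": 0.0,
            "true_te_log2fc": 0.0,
            "true_protein_log2fc": 0.0,
            "category": "null",
        }
    ).set_index("gene_id")
    truth["mean_expression"] = rng.lognormal(mean_log, mean_sigma, size=config.n_genes)

    pool = list(truth.index[int(plant_marker):])
    rng.shuffle(pool)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        picked = pool[cursor : cursor + k]
        cursor += k
        return picked

    up = take(n_mrna_up)
    down = take(n_mrna_down)
    lo, hi = mrna_log2fc_range
    truth.loc[up, "true_mrna_log2fc"] = rng.uniform(lo, hi, size=len(up))
    truth.loc[down, "true_mrna_log2fc"] = -rng.uniform(lo, hi, size=len(down))

    te_genes = take(n_te)
    te_signs = rng.choice([-1.0, 1.0], size=len(te_genes))
    truth.loc[te_genes, "true_te_log2fc"] = te_signs * te_log2fc
    truth.loc[te_genes, "category"] = "te_only"

    # Protein changes driven by the transcriptional effect.
    mrna_genes = up + down
    prot_from_mrna = list(rng.choice(mrna_genes, size=n_protein_from_mrna, replace=False))
    truth.loc[prot_from_mrna, "true_protein_log2fc"] = truth.loc[
        prot_from_mrna, "true_mrna_log2fc"
    ]
    truth.loc[prot_from_mrna, "category"] = "mrna_only"

    # Protein changes with no mRNA/TE support (post-translational).
    orphan = take(n_protein_unexplained)
    lo_u, hi_u = unexplained_log2fc_range
    truth.loc[orphan, "true_protein_log2fc"] = rng.choice(
        [-1.0, 1.0], size=len(orphan)
    ) * rng.uniform(lo_u, hi_u, size=len(orphan))
    truth.loc[orphan, "category"] = "unexplained"

    if plant_marker:
        truth.loc[MARKER_GENE, "true_mrna_log2fc"] = np.log2(3.8)
        truth.loc[MARKER_GENE, "true_te_log2fc"] = np.log2(2.5)
        truth.loc[MARKER_GENE, "true_protein_log2fc"] = np.log2(4.7)
        truth.loc[MARKER_GENE, "category"] = "both"
        # A well-expressed gene: one sigma above the median expression.
        truth.loc[MARKER_GENE, "mean_expression"] = float(np.exp(mean_log + mean_sigma))

    if (~np.isfinite(truth[["true_mrna_log2fc", "true_te_log2fc",
                            "true_protein_log2fc"]].to_numpy())).any():
        raise ConfigurationError("planted fold changes must be finite")
    return truth


def simulate_footprints(
    annotation: Annotation,
    config: SimulationConfig,
    per_gene_abundance: pd.Series | dict,
    n_reads: int | None = None,
    sample_id: str = "WT_1",
    placement: str = "cds_periodic",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulated footprint alignments in transcript coordinates.

    With ``placement='cds_periodic'`` each 5' end falls on a uniformly
    chosen codon of the CDS with frame 0 probability ``frame0_prob``
    (frames 1/2 equiprobable otherwise); ``placement='uniform'`` draws 5'
    ends uniformly over the whole transcript, emulating mRNA-seq reads.
    Read counts per gene are multinomial, proportional to abundance;
    lengths are uniform over ``read_length_range``.
    """
    if placement not in ("cds_periodic", "uniform"):
        raise ValueError("placement must be 'cds_periodic' or 'uniform'")
    if rng is None:
        rng = config.rng("footprints")
    abundance = pd.Series(per_gene_abundance, dtype=float)
    if (abundance < 0).any():
        raise ValueError("abundances must be >= 0")
    known = set(annotation.gene_ids)
    missing = [g for g in abundance.index if g not in known]
    if missing:
        raise KeyError(f"gene(s) absent from annotation: {missing[:10]}")
    total = abundance.sum()
    if n_reads is None:
        n_reads = config.library_size
    if total == 0 or n_reads == 0:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)

    transcripts = {g: annotation.transcripts_of_gene(g)[0] for g in abundance.index}
    gene_order = list(abundance.index)
    counts = rng.multinomial(n_reads, (abundance / total).to_numpy())

    tids = np.repeat([transcripts[g].transcript_id for g in gene_order], counts)
    utr5 = np.repeat([transcripts[g].utr5_len for g in gene_order], counts)
    n_codons = np.repeat(
        [transcripts[g].cds_len // 3 for g in gene_order], counts
    )
    total_len = np.repeat([transcripts[g].total_len for g in gene_order], counts)
    n = len(tids)

    if placement == "cds_periodic":
        codon = rng.integers(0, n_codons)
        p0 = config.frame0_prob
        frame = rng.choice(3, size=n, p=[p0, (1 - p0) / 2, (1 - p0) / 2])
        pos = utr5 + 3 * codon + frame
    else:
        pos = rng.integers(0, total_len)

    lo, hi = config.read_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    return pd.DataFrame(
        {
            "transcript_id": tids,
            "five_prime_pos": pos.astype(np.int64),
            "read_length": lengths.astype(np.int64),
            "sample_id": sample_id,
        }
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + alpha*mu^2 (Poisson if alpha=0)."""
    if alpha < 0:
        raise ConfigurationError("nb_dispersion must be >= 0")
    if alpha == 0:
        return rng.poisson(mu)
    rate = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(rate)


def _sample_design(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    wt, mut = config.conditions
    samples = [f"{wt}_{i + 1}" for i in range(config.n_replicates)] + [
        f"{mut}_{i + 1}" for i in range(config.n_replicates)
    ]
    conditions = pd.Series(
        [wt] * config.n_replicates + [mut] * config.n_replicates,
        index=samples,
        name="condition",
    )
    return samples, conditions


def simulate_counts(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[CountMatrix, CountMatrix, CountMatrix]:
    """NB count matrices (mRNA, RPF, polysomal) from the planted truth.

    The mRNA mean carries only the transcriptional effect,
    mu = mean_expression * 2^(mrna_log2fc * I[mut]); the RPF mean carries
    the transcriptional and TE effects multiplicatively; the polysomal
    matrix is an independent RPF-like realization.  Deterministic given
    the config seed.
    """
    samples, conditions = _sample_design(config)
    is_mut = (conditions == config.conditions[1]).to_numpy(dtype=float)
    base = truth["mean_expression"].to_numpy()[:, None]
    mrna_lfc = truth["true_mrna_log2fc"].to_numpy()[:, None]
    te_lfc = truth["true_te_log2fc"].to_numpy()[:, None]
    mu_mrna = base * 2.0 ** (mrna_lfc * is_mut[None, :])
    mu_rpf = base * 2.0 ** ((mrna_lfc + te_lfc) * is_mut[None, :])

    matrices = []
    for stream, mu in (("mrna", mu_mrna), ("rpf", mu_rpf), ("polysomal", mu_rpf)):
        rng = config.rng(stream)
        counts = _nb_draw(rng, mu, config.nb_dispersion)
        frame = pd.DataFrame(counts, index=truth.index, columns=samples)
        frame.index.name = "gene_id"
        matrices.append(CountMatrix(frame, conditions))
    return tuple(matrices)


def simulate_proteins(
    truth: pd.DataFrame,
    noise_sd: float = 0.3,
    config: SimulationConfig | None = None,
) -> ProteinTable:
    """Log2 protein abundances: baseline + planted effect + Gaussian noise,
    with ``config.n_replicates`` replicates per condition."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if config is None:
        raise ConfigurationError("a SimulationConfig (with seed) is required")
    rng = config.rng("proteins")
    samples, conditions = _sample_design(config)
    is_mut = (conditions == config.conditions[1]).to_numpy(dtype=float)
    baseline = np.log2(truth["mean_expression"].to_numpy() + 1.0)[:, None]
    effect = truth["true_protein_log2fc"].to_numpy()[:, None] * is_mut[None, :]
    noise = rng.normal(0.0, noise_sd, size=(len(truth), len(samples)))
    values = pd.DataFrame(baseline + effect + noise, index=truth.index, columns=samples)
    values.index.name = "gene_id"
    return ProteinTable(values, conditions)


def simulate_mdv(
    true_labeling,
    formula: str,
    noise_sd: float = 0.0,
    seed: int | None = None,
    metabolite: str = "metabolite",
) -> MDV:
    """Observed (uncorrected) MDV: the correction matrix applied to the
    true labeling, plus optional truncated Gaussian noise, renormalized."""
    x = np.asarray(true_labeling, dtype=float)
    if (x < 0).any():
        raise ValueError("true labeling must be nonnegative")
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValueError("true labeling must sum to 1")
    n = parse_formula(formula).get("C", 0)
    if len(x) != n + 1:
        raise ValueError(f"labeling length {len(x)} != tracer atoms + 1 ({n + 1})")
    matrix = build_correction_matrix(formula)
    observed = matrix @ x
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sd > 0")
        rng = np.random.default_rng(np.random.SeedSequence([seed, STREAMS["mdv"]]))
        observed = np.clip(observed + rng.normal(0.0, noise_sd, size=len(observed)), 0.0, None)
    observed = observed / observed.sum()
    return MDV(metabolite=metabolite, formula=formula, values=observed, corrected=False)
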