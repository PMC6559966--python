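"""Differential expression and differential translation efficiency.

Counts are normalized by median-of-ratios size factors.  Differential
expression uses a negative-binomial Wald test: the per-gene dispersion
(Var = mu + alpha * mu^2) is estimated by method of moments and shrunk
toward a trend fitted across genes, and the delta-method standard error
of the log2 fold change yields a two-sided normal p-value.

Translation efficiency (TE) is the ratio of footprint to mRNA counts,
TE = RPF/mRNA; the differential-TE statistic compares mean log TE between
conditions with a z-test whose variance is an empirical-Bayes moderated
replicate variance, floored by the Poisson counting noise of the
underlying counts.  All p-values are Benjamini-Hochberg corrected except
the protein t-test, which is thresholded on the raw p-value.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ProteinTable

__all__ = [
    "benjamini_hochberg",
    "normalize_counts",
    "estimate_dispersions",
    "differential_expression",
    "consistent_de",
    "compute_te",
    "differential_te",
    "protein_differential",
]

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_counts(cm: CountMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized count matrix.

    For genes with nonzero counts in all samples, the size factor of
    sample j is the median of count_gj / geometric-mean_g; normalized
    counts are raw counts divided by the sample's size factor.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter the matrix "
            "(e.g. filter_low_coverage) before normalizing"
        )
    logc = np.log(counts[all_positive])
    log_geomean = logc.mean(axis=1)
    sf = np.exp(np.median(logc - log_geomean[:, None], axis=0))
    size_factors = pd.Series(sf, index=cm.counts.columns, name="size_factor")
    normalized = cm.counts / size_factors
    return size_factors, normalized


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _condition_split(cm: CountMatrix, reference: str) -> tuple[str, list[str], list[str]]:
    labels = list(dict.fromkeys(cm.conditions))
    if len(labels) != 2:
        raise ValueError(f"exactly two conditions required, got {labels}")
    if reference not in labels:
        raise ValueError(f"reference condition {reference!r} not in {labels}")
    treatment = next(lab for lab in labels if lab != reference)
    return treatment, cm.samples_of(reference), cm.samples_of(treatment)


def estimate_dispersions(
    normalized: pd.DataFrame,
    conditions: pd.Series,
    shrinkage_weight: float | None = None,
    min_dispersion: float = 1e-8,
    max_dispersion: float = 10.0,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-gene NB dispersion, shrunk toward a mean-dispersion trend.

    The raw estimate pools within-condition moments:
    alpha_hat = sum_c (n_c-1)(s2_c - m_c) / sum_c (n_c-1) m_c^2.
    The trend is a robust (Theil-Sen) line of log alpha on log mean fitted
    through binwise moment averages.

    With ``shrinkage_weight=None`` (default) the per-gene estimate is
    moderated adaptively: the ratio of the pooled gene variance to the
    trend-implied NB variance is shrunk toward its empirical-Bayes prior,
    so homogeneous data collapse onto the trend while genuinely variable
    dispersions retain per-gene information.  A float in [0, 1] instead
    takes the fixed linear blend ``w * max(alpha_hat, 0) + (1-w) * trend``.
    """
    means, wnum, wden = [], [], []
    for label in dict.fromkeys(conditions):
        cols = conditions[conditions == label].index
        block = normalized[cols].to_numpy(dtype=float)
        n = block.shape[1]
        if n < 2:
            raise ValueError(
                f"condition {label!r} has {n} replicate(s); at least 2 required "
                "for a variance estimate"
            )
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        means.append(m)
        wnum.append((n - 1) * (v - m))
        wden.append((n - 1) * m**2)
    overall_mean = np.mean(means, axis=0)
    num = np.sum(wnum, axis=0)
    den = np.sum(wden, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)

    # Binwise trend: average the (unbiased) moment estimates within
    # expression bins, then fit a robust line in log-log space.
    usable = np.isfinite(alpha_raw) & (overall_mean > 0)
    log_mean = np.log(np.maximum(overall_mean, 1e-300))
    alpha_trend = np.full(len(overall_mean), np.nan)
    if usable.sum() >= 10:
        k = int(min(n_bins, max(usable.sum() // 50, 2)))
        bins = pd.qcut(log_mean[usable], q=k, duplicates="drop")
        grouped = pd.DataFrame(
            {"alpha": alpha_raw[usable], "logm": log_mean[usable], "bin": bins}
        ).groupby("bin", observed=True)
        bin_alpha = grouped["alpha"].mean()
        bin_logm = grouped["logm"].mean()
        good = bin_alpha > 0
        if good.sum() >= 2:
            slope, intercept, *_ = stats.theilslopes(
                np.log(bin_alpha[good]), bin_logm[good]
            )
            alpha_trend = np.exp(intercept + slope * log_mean)
        elif good.sum() == 1:
            alpha_trend = np.full(len(overall_mean), float(bin_alpha[good].iloc[0]))
    if np.isnan(alpha_trend).all():
        # Too few genes for a trend: fall back to the global moment average.
        fallback = np.nanmean(np.clip(alpha_raw, 0, max_dispersion)) if usable.any() else 0.0
        alpha_trend = np.full(len(overall_mean), max(fallback, min_dispersion))
    alpha_trend = np.clip(alpha_trend, min_dispersion, max_dispersion)

    if shrinkage_weight is None:
        # Moderate the ratio of pooled gene variance to the trend-implied
        # NB variance; under the trend the ratio is ~ chi2_df / df.
        df_total = sum(
            (conditions == label).sum() - 1 for label in dict.fromkeys(conditions)
        )
        # pooled within-condition variance, df-weighted
        s2_blocks = []
        for label in dict.fromkeys(conditions):
            cols = conditions[conditions == label].index
            block = normalized[cols].to_numpy(dtype=float)
            s2_blocks.append((block.shape[1] - 1) * block.var(axis=1, ddof=1))
        pooled_s2 = np.sum(s2_blocks, axis=0) / df_total
        model_var = np.maximum(overall_mean + alpha_trend * overall_mean**2, 1e-300)
        ratio = pooled_s2 / model_var
        d0, r0 = _fit_scaled_inv_chisq(ratio, float(df_total))
        if np.isinf(d0):
            ratio_mod = np.full_like(ratio, r0)
        else:
            ratio_mod = (d0 * r0 + df_total * ratio) / (d0 + df_total)
        s2_mod = ratio_mod * model_var
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(
                overall_mean > 0,
                (s2_mod - overall_mean) / np.maximum(overall_mean, 1e-300) ** 2,
                alpha_trend,
            )
    else:
        w = float(shrinkage_weight)
        alpha = w * np.clip(np.nan_to_num(alpha_raw, nan=0.0), 0.0, max_dispersion) + (
            1.0 - w
        ) * alpha_trend
    alpha = np.clip(alpha, min_dispersion, max_dispersion)
    return pd.DataFrame(
        {
            "mean": overall_mean,
            "alpha_raw": alpha_raw,
            "alpha_trend": alpha_trend,
            "alpha": alpha,
        },
        index=normalized.index,
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    cm: CountMatrix,
    pseudocount: float = 0.5,
    reference: str = "WT",
    shrinkage_weight: float | None = None,
) -> pd.DataFrame:
    """NB Wald test per gene: log2fc of normalized condition means with a
    delta-method standard error under Var = mu + alpha*mu^2.

    Returns a table with mean_norm_wt, mean_norm_mut, log2fc, se, z, p, fdr.
    """
    treatment, ref_samples, alt_samples = _condition_split(cm, reference)
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    _, normalized = normalize_counts(cm)
    disp = estimate_dispersions(normalized, cm.conditions, shrinkage_weight)
    alpha = disp["alpha"].to_numpy()

    m_ref = normalized[ref_samples].mean(axis=1).to_numpy()
    m_alt = normalized[alt_samples].mean(axis=1).to_numpy()
    c = float(pseudocount)
    log2fc = np.log2((m_alt + c) / (m_ref + c))

    def var_log2_mean(m: np.ndarray, n: int) -> np.ndarray:
        var_mean = (m + alpha * m**2) / n
        return var_mean / ((m + c) ** 2 * LN2**2)

    se = np.sqrt(
        var_log2_mean(m_ref, len(ref_samples)) + var_log2_mean(m_alt, len(alt_samples))
    )
    z = np.zeros_like(log2fc)
    nonzero = se > 0
    z[nonzero] = log2fc[nonzero] / se[nonzero]
    p = 2.0 * stats.norm.sf(np.abs(z))
    result = pd.DataFrame(
        {
            "mean_norm_wt": m_ref,
            "mean_norm_mut": m_alt,
            "log2fc": log2fc,
            "se": se,
            "z": z,
            "p": p,
            "fdr": benjamini_hochberg(p),
        },
        index=cm.counts.index,
    )
    result.index.name = "gene_id"
    return result


def consistent_de(
    de_results: list[pd.DataFrame] | dict[str, pd.DataFrame],
    fdr_threshold: float = 0.1,
) -> tuple[set[str], set[str]]:
    """Genes significantly up (or down) in *every* dataset.

    A gene is in the up set iff fdr < threshold and log2fc > 0 in all
    result tables; symmetrically for down.  The sets are disjoint.
    """
    tables = list(de_results.values()) if isinstance(de_results, dict) else list(de_results)
    if len(tables) < 2:
        raise ValueError("consistency requires at least 2 result sets")
    shared = tables[0].index
    for t in tables[1:]:
        shared = shared.intersection(t.index)
    up = set(shared)
    down = set(shared)
    for t in tables:
        sub = t.loc[list(shared)]
        sig = sub["fdr"] < fdr_threshold
        up &= set(sub.index[sig & (sub["log2fc"] > 0)])
        down &= set(sub.index[sig & (sub["log2fc"] < 0)])
    return up, down


# ---------------------------------------------------------------------------
# translation efficiency
# ---------------------------------------------------------------------------

def _pair_samples(
    rpf: CountMatrix, mrna: CountMatrix
) -> list[tuple[str, str, str]]:
    """Pair RPF and mRNA replicates positionally within each condition."""
    pairs = []
    rpf_labels = sorted(set(rpf.conditions))
    if rpf_labels != sorted(set(mrna.conditions)):
        raise ValueError(
            f"condition labels differ: {rpf_labels} vs {sorted(set(mrna.conditions))}"
        )
    for label in dict.fromkeys(rpf.conditions):
        a = sorted(rpf.samples_of(label))
        b = sorted(mrna.samples_of(label))
        if len(a) != len(b):
            raise ValueError(
                f"condition {label!r}: {len(a)} RPF vs {len(b)} mRNA replicates"
            )
        pairs.extend((label, x, y) for x, y in zip(a, b))
    return pairs


def compute_te(
    rpf_counts: CountMatrix,
    mrna_counts: CountMatrix,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene, per-replicate translation efficiency TE = RPF/mRNA.

    Each assay is size-factor normalized first; TE_gj =
    (rpf_norm + c) / (mrna_norm + c) for positionally paired replicates.
    Columns are named after the RPF samples.
    """
    if not rpf_counts.counts.index.equals(mrna_counts.counts.index):
        raise ValueError("RPF and mRNA matrices must share the same gene index")
    pairs = _pair_samples(rpf_counts, mrna_counts)
    _, rpf_norm = normalize_counts(rpf_counts)
    _, mrna_norm = normalize_counts(mrna_counts)
    c = float(pseudocount)
    te = pd.DataFrame(
        {
            rs: (rpf_norm[rs] + c) / (mrna_norm[ms] + c)
            for _, rs, ms in pairs
        }
    )
    te.index = rpf_counts.counts.index
    return te


def _fit_scaled_inv_chisq(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene-wise variances.

    Method of moments on log variances: the sampling distribution of
    log(s2) around log(sigma2) has mean digamma(df/2) - log(df/2) and
    variance trigamma(df/2); excess spread across genes identifies the
    prior degrees of freedom d0 (infinite when variances look homogeneous).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    mean_e = float(np.mean(e))
    if excess <= 1e-8:
        return np.inf, float(np.exp(mean_e))
    # invert trigamma(d0/2) = excess by bisection
    lo, hi = 1e-3, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > excess:
            lo = mid
        else:
            hi = mid
    d0 = 2.0 * 0.5 * (lo + hi)
    s0 = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def differential_te(
    rpf_counts: CountMatrix,
    mrna_counts: CountMatrix,
    pseudocount: float = 0.5,
    reference: str = "WT",
    moderate_variance: bool = True,
) -> pd.DataFrame:
    """Two-sided z-test on the difference in mean log TE between conditions.

    Per replicate, logTE = ln TE; Delta = mean(mut) - mean(wt).  The
    variance of Delta is the pooled replicate variance of logTE, moderated
    across genes (empirical-Bayes shrinkage of gene variances toward a
    common prior), and floored by the Poisson counting noise
    sum_j [1/(K_rpf+c) + 1/(K_mrna+c)] / n_c^2 of the raw counts.
    Reported log2_te_ratio = Delta / ln 2; fdr is BH across genes.

    Genes should be pre-filtered with ``filter_low_coverage``; a gene with
    zero counts in every sample of any assay raises an error.
    """
    treatment, _, _ = _condition_split(rpf_counts, reference)
    zero_rpf = (rpf_counts.counts == 0).all(axis=1)
    zero_mrna = (mrna_counts.counts == 0).all(axis=1)
    dead = rpf_counts.counts.index[np.asarray(zero_rpf | zero_mrna)]
    if len(dead):
        raise ValueError(
            f"{len(dead)} gene(s) have zero coverage in an assay "
            f"(e.g. {list(dead[:5])}); apply filter_low_coverage first"
        )
    te = compute_te(rpf_counts, mrna_counts, pseudocount)
    logte = np.log(te.to_numpy())
    pairs = _pair_samples(rpf_counts, mrna_counts)
    c = float(pseudocount)

    cond_stats: dict[str, dict] = {}
    for label in (reference, treatment):
        cols = [i for i, (lab, _, _) in enumerate(pairs) if lab == label]
        if len(cols) < 2:
            raise ValueError(f"condition {label!r} needs >= 2 replicates")
        block = logte[:, cols]
        rpf_raw = rpf_counts.counts[[pairs[i][1] for i in cols]].to_numpy(float)
        mrna_raw = mrna_counts.counts[[pairs[i][2] for i in cols]].to_numpy(float)
        n = len(cols)
        floor = (1.0 / (rpf_raw + c) + 1.0 / (mrna_raw + c)).sum(axis=1) / n**2
        cond_stats[label] = {
            "mean": block.mean(axis=1),
            "var": block.var(axis=1, ddof=1),
            "n": n,
            "floor": floor,
        }

    ref, alt = cond_stats[reference], cond_stats[treatment]
    delta = alt["mean"] - ref["mean"]
    n_ref, n_alt = ref["n"], alt["n"]
    df = n_ref + n_alt - 2
    pooled = ((n_ref - 1) * ref["var"] + (n_alt - 1) * alt["var"]) / df
    if moderate_variance:
        d0, s0 = _fit_scaled_inv_chisq(pooled, df)
        if np.isinf(d0):
            pooled_mod = np.full_like(pooled, s0)
        else:
            pooled_mod = (d0 * s0 + df * pooled) / (d0 + df)
    else:
        pooled_mod = pooled
    var_delta = pooled_mod * (1.0 / n_ref + 1.0 / n_alt)
    var_floor = ref["floor"] + alt["floor"]
    se = np.sqrt(np.maximum(var_delta, var_floor))
    z = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    ref_cols = [pairs[i][1] for i, (lab, _, _) in enumerate(pairs) if lab == reference]
    alt_cols = [pairs[i][1] for i, (lab, _, _) in enumerate(pairs) if lab == treatment]
    result = pd.DataFrame(
        {
            "te_wt": te[ref_cols].mean(axis=1),
            "te_mut": te[alt_cols].mean(axis=1),
            "log2_te_ratio": delta / LN2,
            "log2fc": delta / LN2,  # alias used by downstream integration
            "se": se,
            "z": z,
            "p": p,
            "fdr": benjamini_hochberg(p),
        },
        index=te.index,
    )
    result.index.name = "gene_id"
    return result


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def protein_differential(
    proteins: ProteinTable,
    reference: str = "WT",
    significance_p: float = 0.01,
    variance_floor: float = 1e-8,
) -> pd.DataFrame:
    """Two-tailed two-sample t-test per gene on log2 normalized spectra.

    No multiple-testing correction; the significance flag uses the raw
    p-value threshold (default 0.01).  Genes with zero variance in both
    groups get p = 1 when the means are equal; otherwise a variance floor
    is applied (and logged) so the statistic stays finite.
    """
    labels = list(dict.fromkeys(proteins.conditions))
    if len(labels) != 2:
        raise ValueError(f"exactly two conditions required, got {labels}")
    if reference not in labels:
        raise ValueError(f"reference condition {reference!r} not in {labels}")
    treatment = next(lab for lab in labels if lab != reference)
    a = proteins.values[proteins.samples_of(reference)].to_numpy(float)
    b = proteins.values[proteins.samples_of(treatment)].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each condition needs >= 2 replicates")
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, p = stats.ttest_ind(b, a, axis=1, equal_var=True)
    degenerate = ~np.isfinite(p) | ~np.isfinite(tstat)
    if degenerate.any():
        equal = degenerate & np.isclose(log2fc, 0.0)
        p = np.where(equal, 1.0, p)
        tstat = np.where(equal, 0.0, tstat)
        hard = degenerate & ~equal
        if hard.any():
            logger.info(
                "variance floor applied to %d zero-variance gene(s)", int(hard.sum())
            )
            n_a, n_b = a.shape[1], b.shape[1]
            se = np.sqrt(variance_floor * (1.0 / n_a + 1.0 / n_b))
            t_floor = log2fc / se
            df = n_a + n_b - 2
            p_floor = 2.0 * stats.t.sf(np.abs(t_floor), df)
            p = np.where(hard, p_floor, p)
            tstat = np.where(hard, t_floor, tstat)
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": tstat,
            "p": p,
            "significant": p < significance_p,
        },
        index=proteins.values.index,
    )
    result.index.name = "gene_id"
    return result
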