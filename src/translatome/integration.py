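"""Multi-omics synthesis of protein, mRNA and translation-efficiency changes.

Each significant protein change is classified by whether it is backed by
a significant, sign-concordant mRNA change, a significant TE change,
both, or neither ("unexplained", pointing at post-translational
regulation).  Companion operations quantify how much protein variation
the transcriptome/translatome explains (OLS), correlate fold changes
between assays, and project samples by PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "classify_protein_changes",
    "IntegrationSummary",
    "explain_variance",
    "RegressionReport",
    "fold_change_correlation",
    "sample_pca",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("both", "mrna_only", "te_only", "unexplained")


@dataclass(frozen=True)
class IntegrationSummary:
    """Counts and percentages of concordance categories."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_total: int


def _status(table: pd.DataFrame, gene: str, fdr_threshold: float) -> str:
    if gene not in table.index:
        return "na"
    row = table.loc[gene]
    if row["fdr"] >= fdr_threshold or row["log2fc"] == 0:
        return "ns"
    return "up" if row["log2fc"] > 0 else "down"


def _supports(status: str, protein_sign: int, require_sign: bool) -> bool:
    if status in ("ns", "na"):
        return False
    if not require_sign:
        return True
    return (status == "up") == (protein_sign > 0)


def classify_protein_changes(
    protein_diffs: pd.DataFrame,
    de_results: dict[str, pd.DataFrame] | list[pd.DataFrame],
    te_results: dict[str, pd.DataFrame] | list[pd.DataFrame],
    protein_p: float = 0.01,
    fdr: float = 0.1,
    require_sign: bool = True,
    mrna_rule: str = "any",
) -> tuple[pd.DataFrame, IntegrationSummary]:
    """Classify significant protein changes by mRNA/TE concordance.

    For each protein with p < ``protein_p``: mRNA evidence means a
    significant (fdr < threshold) change in >= 1 mRNA dataset (or all,
    with ``mrna_rule='all'``) whose sign matches the protein's; TE
    evidence is the union over the TE result tables (footprinting-based
    and/or polysome-based).  Categories: both / mrna_only / te_only /
    unexplained; they partition the significant-protein set.
    """
    if not 0 < protein_p < 1 or not 0 < fdr < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    if mrna_rule not in ("any", "all"):
        raise ValueError("mrna_rule must be 'any' or 'all'")
    de_map = (
        dict(de_results)
        if isinstance(de_results, dict)
        else {f"mrna_{i}": t for i, t in enumerate(de_results)}
    )
    te_map = (
        dict(te_results)
        if isinstance(te_results, dict)
        else {f"te_{i}": t for i, t in enumerate(te_results)}
    )
    if not de_map or not te_map:
        raise ValueError("at least one mRNA and one TE result table required")

    significant = protein_diffs[protein_diffs["p"] < protein_p]
    rows = []
    for gene, prot in significant.iterrows():
        psign = int(np.sign(prot["log2fc"]))
        row: dict = {"gene_id": gene, "protein_log2fc": prot["log2fc"]}
        mrna_votes = []
        for name, table in de_map.items():
            status = _status(table, gene, fdr)
            row[f"mrna_status_{name}"] = status
            if status != "na":
                mrna_votes.append(_supports(status, psign, require_sign))
        te_support = False
        for name, table in te_map.items():
            status = _status(table, gene, fdr)
            row[f"te_status_{name}"] = status
            te_support = te_support or _supports(status, psign, require_sign)
        if not mrna_votes:
            mrna_support = False
        elif mrna_rule == "any":
            mrna_support = any(mrna_votes)
        else:
            mrna_support = all(mrna_votes)
        if mrna_support and te_support:
            category = "both"
        elif mrna_support:
            category = "mrna_only"
        elif te_support:
            category = "te_only"
        else:
            category = "unexplained"
        row["category"] = category
        rows.append(row)

    records = pd.DataFrame(rows)
    if not records.empty:
        records = records.set_index("gene_id")
    n_total = len(records)
    counts = {
        cat: int((records["category"] == cat).sum()) if n_total else 0
        for cat in CATEGORIES
    }
    percentages = {
        cat: (100.0 * counts[cat] / n_total) if n_total else 0.0 for cat in CATEGORIES
    }
    return records, IntegrationSummary(counts, percentages, n_total)


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit of protein fold changes on omic-layer predictors."""

    r_squared: float
    aic: float
    coefficients: pd.Series
    n: int
    predictors: tuple[str, ...]


def explain_variance(
    protein_log2fc: pd.Series, predictors: pd.DataFrame
) -> RegressionReport:
    """OLS of protein log2 fold change on mRNA/TE fold-change predictors.

    Returns R^2 and a Gaussian AIC with k = n_predictors + intercept + 1
    (the residual variance counts as a parameter), so values are
    comparable across implementations.  Collinear predictor columns are
    dropped (earliest kept) with a warning.
    """
    data = pd.concat([protein_log2fc.rename("_y"), predictors], axis=1).dropna()
    if len(data) < 3:
        raise ValueError(f"need >= 3 complete cases, got {len(data)}")
    y = data["_y"].to_numpy(float)
    X = data.drop(columns="_y")

    kept: list[str] = []
    for col in X.columns:
        candidate = X[kept + [col]].to_numpy(float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(candidate)), candidate])) == (
            len(kept) + 2
        ):
            kept.append(col)
        else:
            warnings.warn(f"dropping collinear predictor {col!r}", stacklevel=2)
    design = sm.add_constant(X[kept].to_numpy(float))
    fit = sm.OLS(y, design).fit()
    k = len(kept) + 1 + 1  # slopes + intercept + residual variance
    aic = -2.0 * fit.llf + 2.0 * k
    coefficients = pd.Series(fit.params, index=["intercept"] + kept)
    return RegressionReport(
        r_squared=float(fit.rsquared),
        aic=float(aic),
        coefficients=coefficients,
        n=len(data),
        predictors=tuple(kept),
    )


def fold_change_correlation(
    fc_a: pd.Series, fc_b: pd.Series
) -> tuple[float, int]:
    """Pearson r between two log2 fold-change vectors.

    Genes missing (NaN) in either vector are excluded pairwise; returns
    (r, n_used).  Zero variance in either vector yields (nan, n) with a
    warning.
    """
    paired = pd.concat([fc_a.rename("a"), fc_b.rename("b")], axis=1).dropna()
    n = len(paired)
    if n < 3:
        raise ValueError(f"need >= 3 paired finite values, got {n}")
    a, b = paired["a"].to_numpy(float), paired["b"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance in a fold-change vector; correlation undefined",
                      stacklevel=2)
        return float("nan"), n
    r, _ = stats.pearsonr(a, b)
    return float(r), n


def sample_pca(
    normalized: pd.DataFrame, n_components: int = 2, log_transform: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """PCA of samples on (log-transformed) normalized counts.

    Genes are centered; returns per-sample coordinates and the fraction
    of variance explained by each component.  The number of components is
    truncated to what the design supports.
    """
    if normalized.shape[1] < 3:
        raise ValueError("PCA requires >= 3 samples")
    X = normalized.T.to_numpy(float)
    if log_transform:
        X = np.log2(X + 1.0)
    X = X - X.mean(axis=0)
    n_comp = int(min(n_components, X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=normalized.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    explained = pd.Series(
        pca.explained_variance_ratio_, index=frame.columns, name="variance_explained"
    )
    return frame, explained
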