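"""Non-redundant transcriptome reduction and gene-level feature counting.

Footprints are represented by their 5'-most aligned nucleotide.  CDS
counting excludes reads whose 5' end falls within the first 15 or the
last 5 codons, where ribosomes accumulate independently of elongation;
exon counting (used for mRNA-seq and polysomal RNA-seq reads) counts
every read landing anywhere on the transcript.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import Annotation, TranscriptAnnotation
from .containers import CountMatrix

__all__ = [
    "select_longest_isoforms",
    "count_footprints_cds",
    "count_reads_exonic",
    "filter_low_coverage",
]

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = ["transcript_id", "five_prime_pos", "read_length", "sample_id"]


def select_longest_isoforms(annotation: Annotation) -> Annotation:
    """Reduce to one transcript per gene: the one with maximal total
    length, ties broken by lexicographically smallest transcript_id."""
    best: dict[str, TranscriptAnnotation] = {}
    for t in annotation:
        current = best.get(t.gene_id)
        if (
            current is None
            or t.total_len > current.total_len
            or (t.total_len == current.total_len and t.transcript_id < current.transcript_id)
        ):
            best[t.gene_id] = t
    return Annotation(best[g] for g in annotation.gene_ids)


def _join_annotation(alignments: pd.DataFrame, annotation: Annotation) -> pd.DataFrame:
    referenced = set(alignments["transcript_id"].unique())
    known = {t.transcript_id for t in annotation}
    unknown = sorted(referenced - known)
    if unknown:
        logger.info("dropping %d read(s) on unannotated transcript(s)", len(unknown))
    ann = annotation.df
    joined = alignments.merge(
        ann[["gene_id", "utr5_len", "cds_len", "total_len"]],
        left_on="transcript_id",
        right_index=True,
        how="inner",
    )
    return joined


def _tabulate(
    hits: pd.DataFrame,
    annotation: Annotation,
    sample_ids: list[str],
    conditions: pd.Series,
) -> CountMatrix:
    table = (
        hits.groupby(["gene_id", "sample_id"], sort=False)
        .size()
        .unstack("sample_id", fill_value=0)
    )
    table = table.reindex(
        index=annotation.gene_ids, columns=sample_ids, fill_value=0
    ).fillna(0)
    table.index.name = "gene_id"
    return CountMatrix(table, conditions)


def _resolve_design(
    alignments: pd.DataFrame, conditions: pd.Series | dict | None
) -> tuple[list[str], pd.Series]:
    if conditions is None:
        # Infer the condition as the sample-id prefix before the last "_".
        samples = sorted(alignments["sample_id"].unique())
        conditions = pd.Series(
            {s: s.rsplit("_", 1)[0] for s in samples}, name="condition"
        )
    if isinstance(conditions, dict):
        conditions = pd.Series(conditions, name="condition")
    return list(conditions.index), conditions


def count_footprints_cds(
    alignments: pd.DataFrame,
    annotation: Annotation,
    conditions: pd.Series | dict | None = None,
    exclude_start_codons: int = 15,
    exclude_stop_codons: int = 5,
) -> CountMatrix:
    """Count footprints whose 5' end lies in the CDS, excluding the first
    ``exclude_start_codons`` and last ``exclude_stop_codons`` codons.

    A footprint increments its gene iff its 5' end lies in
    ``[utr5_len + 3*exclude_start_codons, utr5_len + cds_len - 3*exclude_stop_codons)``.
    """
    if exclude_start_codons < 0 or exclude_stop_codons < 0:
        raise ValueError("codon exclusion parameters must be >= 0")
    sample_ids, conditions = _resolve_design(alignments, conditions)
    joined = _join_annotation(alignments, annotation)
    lo = joined["utr5_len"] + 3 * exclude_start_codons
    hi = joined["utr5_len"] + joined["cds_len"] - 3 * exclude_stop_codons
    kept = joined[(joined["five_prime_pos"] >= lo) & (joined["five_prime_pos"] < hi)]
    return _tabulate(kept, annotation, sample_ids, conditions)


def count_reads_exonic(
    alignments: pd.DataFrame,
    annotation: Annotation,
    conditions: pd.Series | dict | None = None,
) -> CountMatrix:
    """Count every read whose 5' end lies within its transcript (exonic
    counting for mRNA-type libraries; no codon exclusions)."""
    sample_ids, conditions = _resolve_design(alignments, conditions)
    joined = _join_annotation(alignments, annotation)
    kept = joined[
        (joined["five_prime_pos"] >= 0)
        & (joined["five_prime_pos"] < joined["total_len"])
    ]
    return _tabulate(kept, annotation, sample_ids, conditions)


def filter_low_coverage(
    primary_counts: CountMatrix,
    matched_mrna_counts: CountMatrix,
    min_reads: int = 10,
) -> pd.Index:
    """Genes with at least ``min_reads`` in every sample of both the
    primary assay (footprints or polysomal reads) and its matched mRNA."""
    a, b = primary_counts.counts, matched_mrna_counts.counts
    if not a.index.equals(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(
            "count matrices must share a gene universe; "
            f"only in primary: {only_a[:10]}, only in mRNA: {only_b[:10]}"
        )
    ok = (a.min(axis=1) >= min_reads) & (b.min(axis=1) >= min_reads)
    return a.index[np.asarray(ok)]
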