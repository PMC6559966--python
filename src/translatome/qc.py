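"""Ribosome-footprint quality control.

Length distribution, triplet periodicity, metagene profiles around the
start and stop codons, and per-gene density tracks.  Every read is
represented solely by its 5'-most aligned nucleotide; no P-site
offsetting is applied.  All operations are pure functions of
(alignments, annotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation

__all__ = [
    "length_distribution",
    "frame_periodicity",
    "metagene_profile",
    "density_profile",
    "MetageneProfile",
]

logger = logging.getLogger(__name__)


def length_distribution(alignments: pd.DataFrame) -> pd.Series:
    """Histogram of read lengths.  Counts sum to the number of alignments."""
    if len(alignments) == 0:
        logger.warning("length_distribution called on an empty alignment set")
        return pd.Series(dtype=np.int64, name="count").rename_axis("read_length")
    hist = alignments["read_length"].value_counts().sort_index()
    hist.name = "count"
    hist.index.name = "read_length"
    return hist


def frame_periodicity(
    alignments: pd.DataFrame, annotation: Annotation
) -> pd.DataFrame:
    """Per read length, the fraction of reads in each translation frame.

    The frame of a read is ``(five_prime_pos - utr5_len) mod 3`` relative
    to the annotated CDS start; only reads whose 5' end lies within the
    CDS are assigned.  Returns a table indexed by read_length with columns
    f0, f1, f2 and n_reads; rows with at least one assigned read have
    fractions summing to 1.
    """
    missing = sorted(
        set(alignments["transcript_id"].unique())
        - {t.transcript_id for t in annotation}
    )
    if missing:
        raise KeyError(f"transcript(s) missing from annotation: {missing[:10]}")
    ann = annotation.df
    joined = alignments.merge(
        ann[["utr5_len", "cds_len"]],
        left_on="transcript_id",
        right_index=True,
        how="left",
    )
    in_cds = joined[
        (joined["five_prime_pos"] >= joined["utr5_len"])
        & (joined["five_prime_pos"] < joined["utr5_len"] + joined["cds_len"])
    ].copy()
    in_cds["frame"] = (in_cds["five_prime_pos"] - in_cds["utr5_len"]) % 3
    counts = (
        in_cds.groupby(["read_length", "frame"]).size().unstack("frame", fill_value=0)
    )
    counts = counts.reindex(columns=[0, 1, 2], fill_value=0)
    totals = counts.sum(axis=1)
    fractions = counts.div(totals, axis=0)
    fractions.columns = ["f0", "f1", "f2"]
    fractions["n_reads"] = totals
    return fractions


@dataclass(frozen=True)
class MetageneProfile:
    """Averaged footprint density around the start or stop codon.

    ``densities`` is indexed by the offset (nt) from the anchor; offset 0
    is the first nucleotide of the start codon (anchor='start') or of the
    stop codon (anchor='stop', i.e. the last three CDS nucleotides).
    Offsets with no covering transcript are NaN, not zero.
    """

    anchor: str
    densities: pd.Series
    n_transcripts: int
    total_mapped: int


def metagene_profile(
    alignments: pd.DataFrame,
    annotation: Annotation,
    anchor: str = "start",
    flank: int = 100,
    min_footprints: int = 256,
) -> MetageneProfile:
    """Metagene profile of footprint 5'-end density around start/stop codons.

    Only transcripts with at least ``min_footprints`` aligned footprints
    and an annotated (nonzero) 5'UTR and 3'UTR are averaged.  Per-offset
    counts are averaged over the transcripts covering that offset and
    divided by the total number of mapped reads in the library.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    offsets = np.arange(-flank, flank + 1)
    total_mapped = len(alignments)

    per_transcript = alignments.groupby("transcript_id").size()
    qualifying = [
        t
        for t in annotation
        if per_transcript.get(t.transcript_id, 0) >= min_footprints
        and t.utr5_len > 0
        and t.utr3_len > 0
    ]
    if not qualifying:
        logger.warning(
            "no transcript passes the %d-footprint threshold; empty profile",
            min_footprints,
        )
        empty = pd.Series(np.nan, index=pd.Index(offsets, name="offset"))
        return MetageneProfile(anchor, empty, 0, total_mapped)

    sums = np.zeros(len(offsets))
    coverage = np.zeros(len(offsets))  # transcripts covering each offset
    by_transcript = dict(iter(alignments.groupby("transcript_id")))
    for t in qualifying:
        anchor_pos = t.cds_start if anchor == "start" else t.stop_codon_start
        positions = anchor_pos + offsets
        valid = (positions >= 0) & (positions < t.total_len)
        reads = by_transcript[t.transcript_id]
        pos_counts = reads["five_prime_pos"].value_counts()
        hits = pos_counts.reindex(positions[valid], fill_value=0).to_numpy()
        sums[valid] += hits
        coverage[valid] += 1

    with np.errstate(invalid="ignore"):
        density = np.where(coverage > 0, sums / np.maximum(coverage, 1), np.nan)
    density = density / total_mapped
    series = pd.Series(density, index=pd.Index(offsets, name="offset"), name="density")
    return MetageneProfile(anchor, series, len(qualifying), total_mapped)


def density_profile(
    alignments: pd.DataFrame,
    annotation: Annotation,
    gene_id: str,
    replicates: list[str],
) -> pd.Series:
    """Per-position footprint density track along one gene's transcript.

    For each replicate, per-position counts of 5' ends are divided by
    that replicate's library size (its total alignments in the input),
    then tracks are averaged across replicates.  Positions span the full
    transcript (5'UTR, CDS, 3'UTR).
    """
    transcripts = annotation.transcripts_of_gene(gene_id)
    if len(transcripts) > 1:
        raise ValueError(
            f"gene {gene_id!r} has {len(transcripts)} transcripts; reduce the "
            "annotation with select_longest_isoforms first"
        )
    t = transcripts[0]
    positions = pd.Index(np.arange(t.total_len), name="position")
    track = np.zeros(t.total_len)
    for sample in replicates:
        lib = alignments[alignments["sample_id"] == sample]
        lib_size = len(lib)
        if lib_size == 0:
            raise ValueError(f"replicate {sample!r} has zero library size")
        on_gene = lib[lib["transcript_id"] == t.transcript_id]
        counts = (
            on_gene["five_prime_pos"].value_counts().reindex(positions, fill_value=0)
        )
        track += counts.to_numpy() / lib_size
    track /= len(replicates)
    return pd.Series(track, index=positions, name=gene_id)
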