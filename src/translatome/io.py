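"""Readers and writers for the package's on-disk formats.

Annotation goes to BED12 (transcript-space: one block, thick region =
CDS, name = ``transcript_id|gene_id``) and to a minimal GTF dialect with
transcript/exon/CDS features.  Alignments travel as a 4-column TSV
fixture (``transcript_id  five_prime_pos  read_length  sample_id``) or as
SAM/BAM against the transcript-space reference with the sample recorded
in the read group.  Count and protein tables are TSV with a ``gene_id``
column plus one column per sample, accompanied by a sample sheet; MDVs
are CSV rows ``metabolite, formula, m0..mn``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import Annotation, TranscriptAnnotation
from .containers import CountMatrix, ProteinTable
from .counting import ALIGNMENT_COLUMNS
from .isotope import MDV

__all__ = [
    "write_annotation_bed12",
    "read_annotation_bed12",
    "write_annotation_gtf",
    "read_annotation_gtf",
    "write_alignments_tsv",
    "read_alignments_tsv",
    "write_alignments_sam",
    "read_alignments_sam",
    "write_count_matrix",
    "read_count_matrix",
    "write_protein_table",
    "read_protein_table",
    "write_mdvs",
    "read_mdvs",
]


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def write_annotation_bed12(annotation: Annotation, path: str | Path) -> None:
    rows = []
    for t in annotation:
        rows.append(
            [
                t.transcript_id,  # chrom: the transcript itself
                0,
                t.total_len,
                f"{t.transcript_id}|{t.gene_id}",
                0,
                "+",
                t.cds_start,
                t.cds_end,
                "0",
                1,
                f"{t.total_len},",
                "0,",
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed12(path: str | Path) -> Annotation:
    frame = pd.read_csv(path, sep="\t", header=None)
    records = []
    for row in frame.itertuples(index=False):
        transcript_id, gene_id = str(row[3]).split("|", 1)
        total = int(row[2]) - int(row[1])
        records.append(
            TranscriptAnnotation(
                transcript_id=transcript_id,
                gene_id=gene_id,
                utr5_len=int(row[6]),
                cds_len=int(row[7]) - int(row[6]),
                utr3_len=total - int(row[7]),
            )
        )
    return Annotation(records)


def write_annotation_gtf(annotation: Annotation, path: str | Path) -> None:
    """Minimal GTF dialect: transcript/exon/CDS features, 1-based closed
    coordinates on the transcript itself."""
    with open(path, "w") as fh:
        for t in annotation:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for feature, start, end in (
                ("transcript", 1, t.total_len),
                ("exon", 1, t.total_len),
                ("CDS", t.cds_start + 1, t.cds_end),
            ):
                fh.write(
                    f"{t.transcript_id}\ttranslatome\t{feature}\t{start}\t{end}"
                    f"\t.\t+\t.\t{attrs}\n"
                )


def read_annotation_gtf(path: str | Path) -> Annotation:
    names = ["seqname", "source", "feature", "start", "end", "score", "strand",
             "frame", "attributes"]
    table = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    attr = table["attributes"].str.extract(
        r'gene_id "(?P<gene_id>[^"]+)";\s*transcript_id "(?P<transcript_id>[^"]+)";'
    )
    table = pd.concat([table, attr], axis=1)
    records = []
    for tid, group in table.groupby("transcript_id", sort=False):
        transcript = group[group["feature"] == "transcript"].iloc[0]
        cds = group[group["feature"] == "CDS"].iloc[0]
        total = int(transcript["end"])
        utr5 = int(cds["start"]) - 1
        cds_len = int(cds["end"]) - utr5
        records.append(
            TranscriptAnnotation(
                transcript_id=str(tid),
                gene_id=str(transcript["gene_id"]),
                utr5_len=utr5,
                cds_len=cds_len,
                utr3_len=total - utr5 - cds_len,
            )
        )
    return Annotation(records)


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

def write_alignments_tsv(alignments: pd.DataFrame, path: str | Path) -> None:
    alignments[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"alignment fixture missing column(s): {missing}")
    return frame[ALIGNMENT_COLUMNS]


def write_alignments_sam(
    alignments: pd.DataFrame, annotation: Annotation, path: str | Path
) -> None:
    """SAM/BAM against the transcript-space reference (mode from suffix);
    the sample id is carried by the read group (RG:SM)."""
    path = Path(path)
    mode = "wb" if path.suffix == ".bam" else "w"
    references = [t.transcript_id for t in annotation]
    lengths = [t.total_len for t in annotation]
    samples = sorted(alignments["sample_id"].unique())
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r, "LN": int(l)} for r, l in zip(references, lengths)],
        "RG": [{"ID": s, "SM": s} for s in samples],
    }
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        tid_of = {r: i for i, r in enumerate(references)}
        for i, row in enumerate(alignments.itertuples(index=False)):
            read = pysam.AlignedSegment(out.header)
            read.query_name = f"read_{i}"
            read.reference_id = tid_of[row.transcript_id]
            read.reference_start = int(row.five_prime_pos)
            read.mapping_quality = 255
            read.cigartuples = [(0, int(row.read_length))]
            read.query_sequence = "N" * int(row.read_length)
            read.set_tag("RG", str(row.sample_id))
            out.write(read)


def read_alignments_sam(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(path)) as fh:
        for read in fh.fetch(until_eof=True):
            rows.append(
                (
                    read.reference_name,
                    read.reference_start,
                    read.query_length or read.infer_query_length(),
                    read.get_tag("RG") if read.has_tag("RG") else "unknown",
                )
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


# --------------------------------------------------------------------------
# count / protein tables
# --------------------------------------------------------------------------

def write_count_matrix(
    cm: CountMatrix, path: str | Path, sample_sheet_path: str | Path | None = None,
    assay: str = "counts",
) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    if sample_sheet_path is not None:
        sheet = pd.DataFrame(
            {
                "sample_id": cm.sample_ids,
                "condition": cm.conditions.to_numpy(),
                "assay": assay,
            }
        )
        sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_count_matrix(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    conditions = sheet.set_index("sample_id")["condition"]
    return CountMatrix(counts, conditions)


def write_protein_table(
    table: ProteinTable, path: str | Path, sample_sheet_path: str | Path | None = None
) -> None:
    table.values.rename_axis("gene_id").to_csv(path, sep="\t")
    if sample_sheet_path is not None:
        pd.DataFrame(
            {
                "sample_id": table.values.columns,
                "condition": table.conditions.to_numpy(),
                "assay": "protein",
            }
        ).to_csv(sample_sheet_path, sep="\t", index=False)


def read_protein_table(path: str | Path, sample_sheet_path: str | Path) -> ProteinTable:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    conditions = sheet.set_index("sample_id")["condition"]
    return ProteinTable(values, conditions)


# --------------------------------------------------------------------------
# MDVs
# --------------------------------------------------------------------------

def write_mdvs(mdvs: list[MDV], path: str | Path) -> None:
    n_max = max(m.n_tracer_atoms for m in mdvs)
    header = ["metabolite", "formula", "corrected"] + [f"m{i}" for i in range(n_max + 1)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for m in mdvs:
            row = [m.metabolite, m.formula, int(m.corrected)]
            row += [f"{v:.10g}" for v in m.values]
            row += [""] * (n_max + 1 - len(m.values))
            writer.writerow(row)


def read_mdvs(path: str | Path) -> list[MDV]:
    frame = pd.read_csv(path)
    value_cols = [c for c in frame.columns if c.startswith("m") and c[1:].isdigit()]
    mdvs = []
    for row in frame.itertuples(index=False):
        values = np.array(
            [getattr(row, c) for c in value_cols if np.isfinite(getattr(row, c))]
        )
        mdvs.append(
            MDV(
                metabolite=str(row.metabolite),
                formula=str(row.formula),
                values=values,
                corrected=bool(getattr(row, "corrected", False)),
            )
        )
    return mdvs
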