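"""Transcript models in transcript coordinates.

All footprint operations in this package work on a non-redundant,
transcript-space reference: each transcript is a linear sequence of
5'UTR, CDS and 3'UTR, with 0-based half-open coordinates.  The CDS
occupies ``[utr5_len, utr5_len + cds_len)``; the final three CDS
nucleotides are treated as the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["TranscriptAnnotation", "Annotation"]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript: UTR/CDS structure in transcript coordinates."""

    transcript_id: str
    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(
                f"{self.transcript_id}: UTR lengths must be >= 0 "
                f"(got utr5={self.utr5_len}, utr3={self.utr3_len})"
            )
        if self.cds_len <= 0:
            raise ValueError(f"{self.transcript_id}: cds_len must be > 0")
        if self.cds_len % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: cds_len={self.cds_len} is not a multiple of 3"
            )

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        """First nucleotide of the start codon (0-based)."""
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        """One past the last CDS nucleotide (half-open)."""
        return self.utr5_len + self.cds_len

    @property
    def stop_codon_start(self) -> int:
        """First nucleotide of the stop codon (last 3 nt of the CDS)."""
        return self.cds_end - 3


class Annotation:
    """A set of transcripts keyed by unique transcript_id.

    Acts as the coordinate frame for all footprint operations.  May hold
    multiple transcripts per gene (see
    :func:`translatome.counting.select_longest_isoforms` for the
    non-redundant reduction).
    """

    def __init__(self, transcripts: Iterable[TranscriptAnnotation]):
        self._records = list(transcripts)
        ids = [t.transcript_id for t in self._records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transcript_id(s): {dupes}")
        self._by_id = {t.transcript_id: t for t in self._records}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TranscriptAnnotation]:
        return iter(self._records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptAnnotation:
        try:
            return self._by_id[transcript_id]
        except KeyError:
            raise KeyError(f"transcript {transcript_id!r} not in annotation") from None

    # -- views ---------------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """Tabular view indexed by transcript_id."""
        frame = pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in self._records],
                "gene_id": [t.gene_id for t in self._records],
                "utr5_len": [t.utr5_len for t in self._records],
                "cds_len": [t.cds_len for t in self._records],
                "utr3_len": [t.utr3_len for t in self._records],
            }
        )
        frame["total_len"] = frame.utr5_len + frame.cds_len + frame.utr3_len
        return frame.set_index("transcript_id")

    @property
    def gene_ids(self) -> list[str]:
        """Unique gene ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self._records:
            seen.setdefault(t.gene_id, None)
        return list(seen)

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptAnnotation]:
        hits = [t for t in self._records if t.gene_id == gene_id]
        if not hits:
            raise KeyError(f"gene {gene_id!r} not in annotation")
        return hits

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Annotation":
        """Build from a table with transcript_id (column or index),
        gene_id, utr5_len, cds_len, utr3_len."""
        if frame.index.name == "transcript_id":
            frame = frame.reset_index()
        return cls(
            TranscriptAnnotation(
                transcript_id=str(row.transcript_id),
                gene_id=str(row.gene_id),
                utr5_len=int(row.utr5_len),
                cds_len=int(row.cds_len),
                utr3_len=int(row.utr3_len),
            )
            for row in frame.itertuples(index=False)
        )
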