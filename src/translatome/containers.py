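"""Shared sample-by-gene data containers.

``CountMatrix`` carries raw nonnegative integer counts for one assay
(mRNA-seq, ribosome footprinting, or polysomal RNA-seq) together with
the condition label of each sample.  ``ProteinTable`` carries log2
normalized spectral abundances from quantitative mass spectrometry with
the same design metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "ProteinTable"]


def _check_design(values: pd.DataFrame, conditions: pd.Series) -> pd.Series:
    if values.columns.duplicated().any():
        raise ValueError("sample ids must be unique")
    conditions = conditions.reindex(values.columns)
    if conditions.isna().any():
        missing = list(conditions[conditions.isna()].index)
        raise ValueError(f"no condition label for sample(s): {missing}")
    if conditions.nunique() < 1:
        raise ValueError("at least one condition required")
    return conditions.astype(str)


@dataclass
class CountMatrix:
    """Gene x sample raw counts with a condition label per sample."""

    counts: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.conditions = _check_design(self.counts, self.conditions)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions[self.conditions == condition].index)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.conditions)


@dataclass
class ProteinTable:
    """Gene x sample log2 normalized spectral abundances."""

    values: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("protein abundances must be finite")
        self.conditions = _check_design(self.values, self.conditions)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions[self.conditions == condition].index)
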