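import numpy as np
import pandas as pd
import pytest

from translatome import Annotation, CountMatrix, SimulationConfig, TranscriptAnnotation


@pytest.fixture
def small_config():
    return SimulationConfig(seed=7, n_genes=50, cds_range=(300, 900))


@pytest.fixture
def toy_annotation():
    """One transcript: 60 nt 5'UTR, 300 nt CDS, 90 nt 3'UTR (total 450)."""
    return Annotation(
        [TranscriptAnnotation("tx1", "geneA", utr5_len=60, cds_len=300, utr3_len=90)]
    )


def make_alignments(rows):
    """rows: (transcript_id, five_prime_pos, read_length, sample_id) tuples."""
    return pd.DataFrame(
        rows, columns=["transcript_id", "five_prime_pos", "read_length", "sample_id"]
    )


@pytest.fixture
def alignment_factory():
    return make_alignments


def make_count_matrix(array, conditions=("WT", "WT", "R98S", "R98S"), genes=None):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = [f"{c}_{i}" for i, c in enumerate(conditions)]
    counts = pd.DataFrame(array, index=genes, columns=samples)
    counts.index.name = "gene_id"
    return CountMatrix(counts, pd.Series(list(conditions), index=samples))


@pytest.fixture
def count_matrix_factory():
    return make_count_matrix
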