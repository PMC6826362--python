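import numpy as np
import pandas as pd
import pytest

from hetexpress.data import CountMatrix, SampleSheet


def make_counts(values, sample_ids=None, gene_ids=None, lengths=1000):
    """Build a CountMatrix from a 2D array-like of integers."""
    mat = np.asarray(values, dtype=np.int64)
    gene_ids = gene_ids or [f"g{i}" for i in range(mat.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(mat.shape[1])]
    if np.isscalar(lengths):
        lengths = pd.Series(int(lengths), index=pd.Index(gene_ids))
    else:
        lengths = pd.Series(lengths, index=pd.Index(gene_ids))
    return CountMatrix(pd.DataFrame(mat, index=gene_ids, columns=sample_ids), lengths)


def two_group_sheet(n_per_group=6, groups=("P1", "P2")):
    mapping = {}
    for g in groups:
        for i in range(n_per_group):
            mapping[f"{g}_{i}"] = g
    return SampleSheet(mapping)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
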