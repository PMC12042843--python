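import numpy as np
import pandas as pd
import pytest

from aireflow.containers import CountMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_counts():
    """6 cells x 4 genes, two cell types, two genotypes, hand-written counts."""
    counts = np.array([
        [1, 0, 2, 5],
        [0, 0, 3, 4],
        [2, 1, 0, 0],
        [4, 2, 1, 0],
        [0, 3, 0, 1],
        [1, 1, 1, 1],
    ])
    genes = ["gA", "gB", "gC", "gD"]
    cells = [f"c{i}" for i in range(6)]
    meta = pd.DataFrame(
        {"cell_type": ["T", "T", "B", "B", "T", "B"],
         "genotype": ["KO", "KO", "KO", "HE", "HE", "HE"],
         "animal": ["a1", "a1", "a2", "a3", "a4", "a3"]},
        index=cells)
    return CountMatrix(counts, genes, cells, meta)
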