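"""Shared helpers for building tiny in-memory fixtures."""

import numpy as np
import pandas as pd

from aireflow.containers import ExpressionMatrix


def expr_from_array(X, scale="linear", genotype=None, group="g"):
    """Wrap a genes x samples array into an ExpressionMatrix with stub metadata."""
    X = np.asarray(X, dtype=float)
    genes = [f"g{i}" for i in range(X.shape[0])]
    samples = [f"s{j}" for j in range(X.shape[1])]
    genotype = genotype or ["WT"] * X.shape[1]
    meta = pd.DataFrame({"genotype": genotype, "group": group,
                         "animal": samples}, index=samples)
    return ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), meta, scale=scale)
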