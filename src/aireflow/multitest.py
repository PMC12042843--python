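"""Multiple-testing adjustments used throughout the pipeline.

Benjamini–Hochberg controls the false-discovery rate for genome-wide tests;
Holm–Bonferroni controls the family-wise error rate for the small families of
per-population comparisons. Both delegate to statsmodels and restore the
caller's input order.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def _validated(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return p


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (q values), input order."""
    p = _validated(pvals)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_holm(pvals) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p values, input order.

    Sorted ascending, the i-th smallest p is multiplied by (m - i + 1); running
    maxima enforce monotonicity and values are capped at 1.
    """
    p = _validated(pvals)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]
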