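"""Bulk and pseudobulk two-group differential expression.

The bulk test is a per-gene Welch two-sample t on log2 values with
Benjamini–Hochberg adjustment; the log2 fold change is mean(KO) minus
mean(control). Single-cell comparisons first collapse cells to
(animal, cell-type) pseudobulk sums, which turns cells into biological
replicates and avoids pseudoreplication. Aire-dependent genes are the
genes significantly downregulated in the KO-vs-control mTEC contrast.

Downregulation is everywhere the signed convention LFC < -1 (KO minus
control); figure legends sometimes print the magnitude instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import CountMatrix, DETable, ExpressionMatrix, GeneSet
from .multitest import adjust_bh

log = logging.getLogger(__name__)

PSEUDOBULK_TARGET_SUM = 1e4


def pseudobulk(counts: CountMatrix, min_cells: int = 10) -> "PseudobulkTable":
    """Sum UMI counts per (animal, cell_type) stratum.

    Strata with fewer than ``min_cells`` cells are dropped with a warning —
    a pseudobulk profile from a handful of cells is too noisy to act as a
    biological replicate.
    """
    if counts.n_cells == 0:
        raise ValueError("empty count matrix")
    meta = counts.cell_meta
    key = list(zip(meta["animal"], meta["cell_type"]))
    frame = pd.DataFrame(counts.counts, columns=counts.gene_ids)
    frame["_animal"] = meta["animal"].to_numpy()
    frame["_cell_type"] = meta["cell_type"].to_numpy()
    frame["_genotype"] = meta["genotype"].to_numpy()

    grouped = frame.groupby(["_animal", "_cell_type", "_genotype"], observed=True)
    sums = grouped[counts.gene_ids].sum()
    sizes = grouped.size()

    keep = sizes >= min_cells
    if (~keep).any():
        dropped = sizes[~keep]
        log.warning("dropping %d pseudobulk strata below min_cells=%d: %s",
                    (~keep).sum(), min_cells, dict(dropped))
    sums = sums[keep.to_numpy()]

    meta_out = sums.index.to_frame(index=False).rename(
        columns={"_animal": "animal", "_cell_type": "cell_type", "_genotype": "genotype"})
    meta_out.index = [f"{a}|{c}" for a, c in zip(meta_out["animal"], meta_out["cell_type"])]
    sums.index = meta_out.index
    return PseudobulkTable(sums, meta_out, n_cells=sizes[keep.to_numpy()].to_numpy())


class PseudobulkTable:
    """(animal x cell_type)-by-gene summed counts with stratum metadata."""

    def __init__(self, sums: pd.DataFrame, meta: pd.DataFrame, n_cells: np.ndarray):
        self.sums = sums  # strata x genes, integer
        self.meta = meta  # strata metadata: animal, cell_type, genotype
        self.n_cells = n_cells

    def lognorm(self, target_sum: float = PSEUDOBULK_TARGET_SUM) -> pd.DataFrame:
        """Library-size normalized log2(1 + target_sum * count / stratum_total)."""
        lib = self.sums.sum(axis=1).to_numpy(dtype=float)[:, None]
        lib[lib == 0] = 1.0
        return np.log2(1.0 + target_sum * self.sums / lib)

    def expression_for(self, cell_type: str) -> ExpressionMatrix:
        """Gene-by-animal log2 ExpressionMatrix for one cell type."""
        mask = (self.meta["cell_type"] == cell_type).to_numpy()
        if not mask.any():
            raise ValueError(f"no pseudobulk strata for cell type {cell_type!r}")
        vals = self.lognorm()[mask].T  # genes x strata
        meta = self.meta[mask].copy()
        meta["group"] = meta["cell_type"]
        return ExpressionMatrix(vals, meta[["genotype", "group", "animal"]], scale="log2")


def de_test(expr: ExpressionMatrix, ko: str = "KO", control: str = "HE") -> DETable:
    """Welch two-sample t per gene on log2 values, KO minus control, BH-adjusted.

    Genes with zero variance in both groups and equal means are assigned
    p = 1 (no evidence either way rather than 0/0).
    """
    expr = expr.to_log2()
    geno = expr.sample_meta.loc[expr.sample_ids, "genotype"]
    ko_cols = [s for s in expr.sample_ids if geno[s] == ko]
    ctl_cols = [s for s in expr.sample_ids if geno[s] == control]
    if len(ko_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError(
            f"need >=2 replicates per group, got {len(ko_cols)} {ko} vs {len(ctl_cols)} {control}")

    A = expr.values[ko_cols].to_numpy(dtype=float)
    B = expr.values[ctl_cols].to_numpy(dtype=float)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = st.ttest_ind(A, B, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    still_bad = np.isnan(p)
    if still_bad.any():  # zero variance but unequal means: infinitely strong evidence
        p[still_bad] = 0.0
    padj = adjust_bh(p)
    table = pd.DataFrame({"lfc": lfc, "p": p, "padj": padj},
                         index=expr.values.index.rename("gene"))
    log.info("DE %s vs %s: %d genes, %d at FDR<0.05",
             ko, control, len(table), int((padj < 0.05).sum()))
    return DETable(table, method="BH")


def define_aire_dependent(de: DETable, lfc_cut: float = -1.0, fdr_cut: float = 0.05) -> GeneSet:
    """Genes downregulated in the KO mTEC contrast: LFC < lfc_cut and FDR < fdr_cut.

    Both inequalities are strict, so a gene sitting exactly on a cut is
    excluded.
    """
    t = de.table
    hit = (t["lfc"] < lfc_cut) & (t["padj"] < fdr_cut)
    genes = list(t.index[hit])
    log.info("Aire-dependent definition (LFC<%g, FDR<%g): %d genes", lfc_cut, fdr_cut, len(genes))
    return GeneSet("aire_dependent", genes)


def de_by_population(pb: PseudobulkTable, ko: str = "KO", control: str = "HE") -> dict[str, DETable]:
    """Pseudobulk Welch-t DE per cell type; skips cell types lacking replicates."""
    tables: dict[str, DETable] = {}
    for ct in sorted(pb.meta["cell_type"].unique()):
        try:
            tables[ct] = de_test(pb.expression_for(ct), ko=ko, control=control)
        except ValueError as exc:
            log.warning("skipping population %r: %s", ct, exc)
    if not tables:
        raise ValueError("no population had >=2 replicates per genotype")
    return tables
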