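"""Tonic-sensitive ISG classification and the per-cell-type IFN score.

A tonic-sensitive interferon-stimulated gene (ISG) is one whose baseline
expression already depends on constitutive interferon-receptor signalling:
operationally, it is downregulated at baseline in an unstimulated
interferon-receptor-knockout reference contrast. The IFN score then asks, per
cell type, how far a knockout animal's tonic-sensitive ISGs sit from the
control distribution: each gene is z-standardized against the control
animals' mean and SD, and the z scores are summed per knockout animal. A
strongly negative score means blunted tonic interferon signalling.

Expression enters the score as a per-animal, per-cell-type mean of
log-normalized values (animal-level aggregation avoids treating cells as
independent replicates). SD uses the n-1 denominator; genes whose control SD
is zero are dropped rather than epsilon-padded, because an epsilon would let
a constant gene dominate the sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DETable, ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)


@dataclass
class TonicLabels:
    """Per-ISG tonic-sensitivity labels with the reference statistics behind them."""

    table: pd.DataFrame  # index gene; columns tonic_sensitive (bool), ref_lfc, ref_fdr, unclassified

    @property
    def tonic_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["tonic_sensitive"] & ~t["unclassified"]])


def classify_tonic(reference_de: DETable, isg_universe: GeneSet,
                   lfc_cut: float = -1.0, fdr_cut: float = 0.05) -> TonicLabels:
    """Split an ISG universe into tonic-sensitive vs tonic-insensitive genes.

    A gene is tonic-sensitive when the baseline receptor-knockout reference
    shows LFC < ``lfc_cut`` and FDR < ``fdr_cut``. ISGs absent from the
    reference are flagged unclassified (and excluded from downstream scores);
    if the reference covers less than half the universe the classification is
    considered unreliable and an error is raised.
    """
    ref = reference_de.table
    covered = [g for g in isg_universe.genes if g in ref.index]
    if len(covered) < len(isg_universe.genes) / 2:
        raise ValueError(
            f"reference covers only {len(covered)}/{len(isg_universe.genes)} ISGs; "
            "classification would be unreliable")
    rows = []
    for g in isg_universe.genes:
        if g in ref.index:
            lfc, fdr = float(ref.loc[g, "lfc"]), float(ref.loc[g, "padj"])
            rows.append((g, lfc < lfc_cut and fdr < fdr_cut, lfc, fdr, False))
        else:
            rows.append((g, False, np.nan, np.nan, True))
    table = pd.DataFrame(rows, columns=["gene", "tonic_sensitive", "ref_lfc", "ref_fdr",
                                        "unclassified"]).set_index("gene")
    n_tonic = int(table["tonic_sensitive"].sum())
    log.info("tonic classification: %d sensitive / %d insensitive / %d unclassified",
             n_tonic, len(table) - n_tonic - int(table["unclassified"].sum()),
             int(table["unclassified"].sum()))
    return TonicLabels(table)


def ifn_score(expr: ExpressionMatrix, tonic: TonicLabels,
              control_ids: list[str], ko_ids: list[str]) -> pd.DataFrame:
    """Standardized-sum IFN score for one cell type.

    ``expr`` holds per-animal expression (genes x animals, log2 scale or any
    per-gene-comparable unit). For every tonic-sensitive gene g,
    z_g = (x_KO,g - mean_ctrl,g) / sd_ctrl,g; the score of a KO animal is the
    sum of its z_g. Genes whose control SD is zero are dropped with a warning.

    Returns a DataFrame indexed by KO animal with columns score, n_genes.
    """
    if len(control_ids) < 2:
        raise ValueError("need >=2 control samples to estimate a control SD")
    genes = [g for g in tonic.tonic_genes if g in expr.values.index]
    if not genes:
        raise ValueError("no tonic-sensitive gene present in the expression matrix")
    ctrl = expr.values.loc[genes, control_ids].to_numpy(dtype=float)
    ko = expr.values.loc[genes, ko_ids].to_numpy(dtype=float)

    mu = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        log.warning("dropping %d tonic genes with zero control SD", int((~keep).sum()))
    if not keep.any():
        raise ValueError("every tonic-sensitive gene has zero control SD")

    z = (ko[keep] - mu[keep, None]) / sd[keep, None]
    scores = z.sum(axis=0)
    return pd.DataFrame({"score": scores, "n_genes": int(keep.sum())},
                        index=pd.Index(ko_ids, name="animal"))


def ifn_score_by_cell_type(per_animal: dict[str, ExpressionMatrix], tonic: TonicLabels) -> pd.DataFrame:
    """IFN scores across cell types; control/KO split read from sample metadata.

    ``per_animal`` maps cell type -> gene-by-animal ExpressionMatrix whose
    sample metadata carries genotype. Returns a tidy frame
    (animal, cell_type, score, n_genes).
    """
    frames = []
    for ct, expr in sorted(per_animal.items()):
        geno = expr.sample_meta.loc[expr.sample_ids, "genotype"]
        ctl = [s for s in expr.sample_ids if geno[s] in ("HE", "WT")]
        ko = [s for s in expr.sample_ids if geno[s] == "KO"]
        res = ifn_score(expr, tonic, ctl, ko)
        res = res.reset_index()
        res.insert(1, "cell_type", ct)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
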