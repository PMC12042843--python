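"""Gene-set enrichment statistics.

Three flavours of set-level analysis:

* Fisher / hypergeometric over-representation of a set among "hit" genes
  (for example interferon-stimulated genes among the genes downregulated in
  knockouts), with the sample (cross-product) odds ratio and a one-sided
  exact tail p value;
* pre-ranked GSEA with the classic weighted running-sum statistic, a
  gene-label permutation null, and signed-mean NES normalization — with gene
  sets downsampled to a common size first so that set size does not confound
  the comparison between sets;
* a per-cell module score: mean expression of the set minus the mean of
  expression-matched control genes drawn from equal-frequency bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import CountMatrix, DETable, GeneSet
from .multitest import adjust_holm

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher over-representation

@dataclass
class EnrichmentResult:
    """2x2 over-representation result. ``a`` counts genes in-set AND hit."""

    population: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    adjusted_p: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_enrichment(universe, hits, gene_set: GeneSet, population: str = "",
                      alternative: str = "greater") -> EnrichmentResult:
    """One-sided exact test for over-representation of ``gene_set`` among ``hits``.

    The set is intersected with the universe before tabulation. p is the
    hypergeometric tail P(X >= a) for alternative="greater" (scipy's exact
    two-sided variant behind alternative="two-sided"). The odds ratio is the
    sample cross-product ad/bc; if any cell is zero it is recomputed with the
    Haldane–Anscombe +0.5 correction and flagged ``haldane``.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ValueError("hits must be a subset of the universe")
    members = set(gene_set.genes) & uni

    a = len(members & hit_set)
    b = len(members - hit_set)
    c = len(hit_set - members)
    d = len(uni) - a - b - c

    flags: list[str] = []
    if a + b == 0:
        flags.append("degenerate")
        return EnrichmentResult(population, a, b, c, d, float("nan"), 1.0, flags=flags)

    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        flags.append("haldane")
    else:
        odds = (a * d) / (b * c)

    if alternative == "greater":
        # tail of Hypergeom(N=universe, K=set size, n=hits)
        p = float(st.hypergeom.sf(a - 1, len(uni), a + b, a + c))
    else:
        _, p = st.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(population, a, b, c, d, float(odds), min(float(p), 1.0), flags=flags)


def enrichment_by_population(de_tables: dict[str, DETable], gene_set: GeneSet,
                             lfc_cut: float = -1.0, fdr_cut: float = 0.05) -> list[EnrichmentResult]:
    """Per-population enrichment of a set among downregulated genes, Holm-adjusted.

    Each population's 2x2 is built on that population's own tested universe.
    Degenerate populations stay in the family (they count toward m in the
    Holm adjustment) and are flagged.
    """
    if not de_tables:
        raise ValueError("no DE tables supplied")
    results = []
    for pop in sorted(de_tables):
        t = de_tables[pop].table
        universe = list(t.index)
        hits = list(t.index[(t["lfc"] < lfc_cut) & (t["padj"] < fdr_cut)])
        res = fisher_enrichment(universe, hits, gene_set, population=pop)
        results.append(res)
    adj = adjust_holm([r.p for r in results])
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "population": r.population, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "odds_ratio": r.odds_ratio, "p": r.p, "holm_p": r.adjusted_p,
            "flags": ";".join(r.flags),
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# pre-ranked GSEA

def downsample_sets(sets: list[GeneSet], rng: np.random.Generator) -> list[GeneSet]:
    """Downsample all sets (without replacement) to the smallest set's size.

    Equalizing size before GSEA removes the set-size dependence of the
    enrichment-score null, so NES values are comparable across sets. Sets
    already at the target size are returned unchanged.
    """
    if not sets:
        raise ValueError("no gene sets supplied")
    target = min(len(s) for s in sets)
    out = []
    for s in sets:
        if len(s) == target:
            out.append(s)
        else:
            keep = sorted(rng.choice(len(s.genes), size=target, replace=False))
            genes = [s.genes[i] for i in keep]
            labels = {g: s.labels[g] for g in genes if g in s.labels} if s.labels else None
            out.append(GeneSet(s.name, genes, labels))
    return out


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    leading_edge: list[str]
    n_perm: int
    set_size: int
    running_sum: pd.Series  # indexed by ranked gene, for trace plots


def gsea_preranked(ranked: pd.Series, gene_set: GeneSet, weight: float = 1.0,
                   n_perm: int = 10000, rng: np.random.Generator | None = None) -> GSEAResult:
    """Classic weighted running-sum GSEA on a pre-ranked gene list.

    ``ranked`` maps gene -> ranking statistic and is sorted descending
    internally. Hits increment the running sum by |s_i|^weight (normalized to
    sum to 1 over the set); misses decrement by 1/(N - set size). ES is the
    signed maximum deviation. The null permutes gene labels (the standard
    choice for pre-ranked input), NES = ES / mean(|null ES| of the matching
    sign) and p is the one-tailed permutation fraction with the +1
    pseudocount.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if ranked.isna().any():
        raise ValueError("ranking statistics contain NaN")
    ranked = ranked.sort_values(ascending=False, kind="stable")
    genes = list(ranked.index)
    stats = ranked.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set.genes))
    n_hit = int(in_set.sum())
    n = len(genes)
    if n_hit == 0:
        raise ValueError(f"set {gene_set.name!r} shares no genes with the ranked list")
    if n_hit == n:
        raise ValueError("set covers the entire ranked list; miss decrement undefined")

    def running(in_set_mask: np.ndarray) -> np.ndarray:
        w = np.abs(stats) ** weight
        hit_w = np.where(in_set_mask, w, 0.0)
        denom = hit_w.sum()
        if denom == 0:  # all-zero statistics: fall back to unweighted steps
            hit_w = in_set_mask.astype(float)
            denom = hit_w.sum()
        steps = hit_w / denom - (~in_set_mask) / (n - in_set_mask.sum())
        return np.cumsum(steps)

    rs = running(in_set)
    i_ext = int(np.argmax(np.abs(rs)))
    es = float(rs[i_ext])

    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_hit, replace=False)] = True
        nrs = running(perm)
        null[i] = nrs[np.argmax(np.abs(nrs))]

    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    mean_abs = float(np.abs(null[same_sign]).mean()) if n_same else float("nan")
    nes = es / mean_abs if (n_same and mean_abs > 0) else float("nan")
    exceed = int((np.abs(null[same_sign]) >= abs(es)).sum())
    p = (1 + exceed) / (n_same + 1)

    if es >= 0:
        leading = [g for g, m in zip(genes[: i_ext + 1], in_set[: i_ext + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[i_ext:], in_set[i_ext:]) if m]

    log.info("GSEA %s: ES=%.3f NES=%.3f p=%.2g (%d/%d genes, %d perms)",
             gene_set.name, es, nes, p, n_hit, n, n_perm)
    return GSEAResult(gene_set.name, es, nes, float(p), leading, n_perm, n_hit,
                      pd.Series(rs, index=genes, name="running_es"))


# ---------------------------------------------------------------------------
# per-cell module score

def module_score(counts: CountMatrix, gene_set: GeneSet, n_bins: int = 24,
                 n_ctrl: int = 100, rng: np.random.Generator | None = None) -> pd.Series:
    """Per-cell signature score: set mean minus expression-matched control mean.

    Genes are placed into ``n_bins`` equal-frequency bins of average
    log-normalized expression; each set gene contributes ``n_ctrl`` control
    genes sampled from its own bin (with replacement when the bin is
    smaller), so the control matches the set's expression profile.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = counts.lognorm()
    genes = counts.gene_ids
    idx = {g: i for i, g in enumerate(genes)}
    members = [g for g in gene_set.genes if g in idx]
    if not members:
        raise ValueError(f"set {gene_set.name!r} shares no genes with the count matrix")

    avg = X.mean(axis=0)
    n_bins = min(n_bins, len(genes))
    # equal-frequency bins with random jitter-free rank binning
    ranks = st.rankdata(avg, method="ordinal") - 1
    bins = (ranks * n_bins // len(genes)).astype(int)

    ctrl_cols = []
    for g in members:
        pool = np.flatnonzero(bins == bins[idx[g]])
        replace = len(pool) < n_ctrl
        ctrl_cols.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_cols)

    set_mean = X[:, [idx[g] for g in members]].mean(axis=1)
    ctrl_mean = X[:, ctrl_idx].mean(axis=1)
    return pd.Series(set_mean - ctrl_mean, index=counts.cell_ids,
                     name=f"score_{gene_set.name}")
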