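"""Cross-species comparison of Aire-regulated gene programs.

Rat and mouse knockout differential-expression results are combined over a
one-to-one ortholog map into a gene-by-dataset log2-fold-change matrix.
Downstream: PCA of samples restricted to Aire-regulated genes, K-means gene
modules on the scaled LFC matrix (the conserved module is the one
downregulated in every dataset), Fisher enrichment of each module in
TRA/ISG sets, correlation-distance hierarchical clustering of populations
with plain bootstrap support proportions, and Spearman comparison of
relative expression between datasets.

Missing LFC entries are genuinely absent (NaN), never zero; they are imputed
as 0 only inside the clustering step (flagged) and never enter enrichment
universes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats as st
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import DETable, GeneSet
from .enrich import EnrichmentResult, fisher_enrichment
from .multitest import adjust_holm

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ortholog combination

def filter_one_to_one(ortholog_map: pd.DataFrame) -> pd.DataFrame:
    """Drop every rat or mouse gene that appears more than once in the map."""
    m = ortholog_map.drop_duplicates(subset=["rat_gene", "mouse_gene"])
    m = m[~m["rat_gene"].duplicated(keep=False)]
    m = m[~m["mouse_gene"].duplicated(keep=False)]
    return m.reset_index(drop=True)


def combine_orthologs(rat_de: DETable, mouse_des: dict[str, DETable],
                      ortholog_map: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-dataset LFC matrix over orthologs (rat gene ids as row index).

    Rows are genes present in the rat table and at least one mouse dataset;
    a gene missing from a dataset is NaN in that column only.
    """
    if ortholog_map["rat_gene"].duplicated().any() or ortholog_map["mouse_gene"].duplicated().any():
        raise ValueError("ortholog map is not one-to-one; filter it first")
    m2r = dict(zip(ortholog_map["mouse_gene"], ortholog_map["rat_gene"]))

    cols = {"rat": rat_de.table["lfc"]}
    for name, de in mouse_des.items():
        lfc = de.table["lfc"].copy()
        lfc.index = [m2r.get(g, g) for g in lfc.index]
        lfc = lfc[~lfc.index.duplicated()]
        cols[name] = lfc
    combined = pd.DataFrame(cols)
    in_rat = combined["rat"].notna()
    in_any_mouse = combined.drop(columns="rat").notna().any(axis=1)
    combined = combined[in_rat & in_any_mouse]
    log.info("combined ortholog LFC matrix: %d genes x %d datasets (union policy: "
             "rat AND >=1 mouse)", *combined.shape)
    return combined


# ---------------------------------------------------------------------------
# PCA of samples on Aire-regulated genes

def pca_samples(expr_subset: pd.DataFrame, n_components: int | None = None
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples (rows) on z-scaled genes (columns).

    Zero-variance genes are dropped before scaling. The sign of each
    component is fixed so its largest-magnitude loading is positive, making
    coordinates reproducible across gene/sample orderings.
    Returns (coordinates DataFrame, variance-explained fractions).
    """
    X = expr_subset.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs >=3 samples")
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sds[keep]

    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| positive per component
    for i in range(k):
        j = np.argmax(np.abs(pca.components_[i]))
        if pca.components_[i, j] < 0:
            coords[:, i] *= -1
    out = pd.DataFrame(coords, index=expr_subset.index,
                       columns=[f"PC{i+1}" for i in range(k)])
    return out, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# K-means gene modules

@dataclass
class ModuleAssignment:
    modules: pd.Series      # gene -> module id (1..k), renumbered by descending size
    wcss: float
    imputed: pd.Series      # gene -> True if any entry was imputed for clustering

    @property
    def k(self) -> int:
        return int(self.modules.max())

    def genes_in(self, module: int) -> list[str]:
        return list(self.modules.index[self.modules == module])


def kmeans_modules(lfc_matrix: pd.DataFrame, k: int = 4, n_init: int = 50,
                   rng: np.random.Generator | None = None) -> ModuleAssignment:
    """K-means gene modules on the column-scaled LFC matrix.

    Each dataset column is z-scaled; absent entries are imputed as 0 (the
    scaled mean) for clustering only, and the affected genes are flagged.
    Best of ``n_init`` initializations by within-cluster sum of squares;
    module labels are renumbered by descending module size.
    """
    if k >= len(lfc_matrix):
        raise ValueError(f"k={k} must be below the number of genes ({len(lfc_matrix)})")
    if rng is None:
        rng = np.random.default_rng(0)
    X = lfc_matrix.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    imputed = np.isnan(Z).any(axis=1)
    Z = np.nan_to_num(Z, nan=0.0)

    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(Z)

    sizes = pd.Series(labels).value_counts()
    rank = {old: new + 1 for new, old in enumerate(sizes.index)}
    modules = pd.Series([rank[l] for l in labels], index=lfc_matrix.index, name="module")
    log.info("k-means modules (k=%d): sizes %s, WCSS=%.2f",
             k, modules.value_counts().sort_index().tolist(), km.inertia_)
    return ModuleAssignment(modules, float(km.inertia_),
                            pd.Series(imputed, index=lfc_matrix.index))


def module_set_enrichment(assignment: ModuleAssignment, gene_set: GeneSet
                          ) -> list[EnrichmentResult]:
    """Fisher enrichment of ``gene_set`` inside each module, Holm across modules.

    Universe = all clustered genes; per module the 2x2 crosses in-module with
    in-set membership.
    """
    universe = list(assignment.modules.index)
    results = []
    for mod in range(1, assignment.k + 1):
        hits = assignment.genes_in(mod)
        res = fisher_enrichment(universe, hits, gene_set, population=f"module_{mod}")
        results.append(res)
    adj = adjust_holm([r.p for r in results])
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
    return results


# ---------------------------------------------------------------------------
# hierarchical clustering of populations with bootstrap support

@dataclass
class PopulationDendrogram:
    linkage: np.ndarray
    labels: list[str]
    support: dict[frozenset, float]  # clade (as label set) -> bootstrap proportion

    def newick(self) -> str:
        """Newick string with bootstrap proportions as internal node labels."""
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        for i, (a, b, dist, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            clade = members[a] | members[b]
            sup = self.support.get(clade, float("nan"))
            nodes[n + i] = f"({nodes[a]},{nodes[b]}){sup:.2f}"
            members[n + i] = clade
        return nodes[n + len(self.linkage) - 1] + ";"


def _clades(linkage: np.ndarray, labels: list[str]) -> set[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = set()
    for i, (a, b, *_rest) in enumerate(linkage):
        clade = members[int(a)] | members[int(b)]
        members[n + i] = clade
        if len(clade) < n:  # the root clade is trivial
            clades.add(clade)
    return clades


def cluster_populations(mean_expr: pd.DataFrame, n_boot: int = 1000,
                        rng: np.random.Generator | None = None) -> PopulationDendrogram:
    """Average-linkage clustering of populations on 1 - Pearson, with bootstrap support.

    ``mean_expr`` is population-by-gene. The bootstrap resamples genes with
    replacement, reclusters, and records for every internal clade of the
    original tree the fraction of bootstrap trees containing it (plain
    bootstrap proportion, not a multiscale-corrected value).
    """
    if len(mean_expr) < 3:
        raise ValueError("need >=3 populations to cluster")
    if rng is None:
        rng = np.random.default_rng(0)
    X = mean_expr.to_numpy(dtype=float)
    if (X.std(axis=1) == 0).any():
        bad = list(mean_expr.index[X.std(axis=1) == 0])
        raise ValueError(f"zero-variance populations: {bad}")
    labels = list(mean_expr.index)

    def cluster(M: np.ndarray) -> np.ndarray:
        d = np.clip(ssd.pdist(M, metric="correlation"), 0, None)
        return sch.linkage(d, method="average")

    Z = cluster(X)
    target = _clades(Z, labels)
    counts = {c: 0 for c in target}
    n_genes = X.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        Xb = X[:, idx]
        if (Xb.std(axis=1) == 0).any():
            continue
        for c in _clades(cluster(Xb), labels):
            if c in counts:
                counts[c] += 1
    support = {c: counts[c] / n_boot for c in target}
    return PopulationDendrogram(Z, labels, support)


# ---------------------------------------------------------------------------
# Spearman comparison

def spearman_compare(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p via the t approximation; for n <= 9 the p value is computed
    exactly by enumerating all rank permutations (ties handled by permuting
    the observed tied ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >=5 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p_t = st.spearmanr(x, y)

    n = len(x)
    if n <= 9:
        from itertools import permutations
        rx = st.rankdata(x)
        ry = st.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                hits += 1
        return float(rho), hits / total
    return float(rho), float(p_t)
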