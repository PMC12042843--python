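"""Synthetic data generators with planted, machine-readable ground truth.

Each generator emulates one class of input the pipeline consumes and returns
a :class:`~aireflow.containers.TruthRecord` alongside the data, so every
downstream stage can be scored (recall/precision, Jaccard, adjusted Rand
index) without re-reading generator internals. All generators are pure
functions of their parameters and seed.

Noise models: bulk expression is Gaussian on log2 scale (matching
microarray-style data); single-cell UMI counts are negative-binomial with a
global dispersion — the minimal structure that exercises pseudobulk
differential expression and the IFN score. Doublets, ambient RNA, batch
effects and gene-gene correlation beyond the planted module structure are
deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import CountMatrix, DETable, ExpressionMatrix, GeneSet, TruthRecord
from .multitest import adjust_bh


# ---------------------------------------------------------------------------
# multi-tissue bulk panel with planted tissue-restricted genes

def make_tissue_panel(n_genes: int = 2000, n_tissue_samples: int = 33,
                      n_groups_true: int = 11, n_tra: int = 50,
                      expr_hi: float = 1000.0, expr_lo: float = 10.0,
                      noise_sd: float = 1.0, seed: int = 0
                      ) -> tuple[ExpressionMatrix, TruthRecord]:
    """Multi-tissue linear-scale expression panel with planted TRAs.

    Background genes sit at ``expr_lo`` plus Gaussian noise (truncated at 0)
    everywhere. Each planted TRA instead expresses at ``expr_hi`` in the
    samples of 1-3 randomly chosen tissue groups. Samples within a true group
    are correlated replicates: they share a per-(group, gene) random offset of
    the same magnitude as the sample noise, which is what lets hierarchical
    clustering recover the groups. The truth records each TRA's
    expressing-group count.
    """
    if n_tra > n_genes:
        raise ValueError("n_tra cannot exceed n_genes")
    if expr_hi <= expr_lo or expr_lo < 0:
        raise ValueError("need expr_hi > expr_lo >= 0")
    if n_tissue_samples < n_groups_true:
        raise ValueError("need at least one sample per tissue group")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    group_of_sample = np.arange(n_tissue_samples) % n_groups_true
    samples = [f"S{i:03d}_T{group_of_sample[i]:02d}" for i in range(n_tissue_samples)]

    # shared per-(group, gene) offsets induce within-group correlation
    group_fx = rng.normal(0.0, noise_sd, size=(n_genes, n_groups_true))
    X = expr_lo + group_fx[:, group_of_sample] + rng.normal(0.0, noise_sd,
                                                            size=(n_genes, n_tissue_samples))

    tra_idx = rng.choice(n_genes, size=n_tra, replace=False)
    planted_tra: dict[str, int] = {}
    for gi in tra_idx:
        n_expr = int(rng.integers(1, 4))  # 1-3 expressing groups
        expr_groups = rng.choice(n_groups_true, size=n_expr, replace=False)
        mask = np.isin(group_of_sample, expr_groups)
        X[gi, mask] = expr_hi + group_fx[gi, group_of_sample[mask]] \
            + rng.normal(0.0, noise_sd, size=mask.sum())
        planted_tra[genes[gi]] = n_expr
    X = np.clip(X, 0.0, None)

    values = pd.DataFrame(X, index=genes, columns=samples)
    meta = pd.DataFrame(
        {"genotype": "WT",
         "group": [f"tissue_{g:02d}" for g in group_of_sample],
         "animal": [f"A{i:03d}" for i in range(n_tissue_samples)]},
        index=samples)
    return (ExpressionMatrix(values, meta, scale="linear"),
            TruthRecord(planted_tra=planted_tra))


# ---------------------------------------------------------------------------
# KO-vs-control bulk mTEC transcriptomes with planted Aire-dependent genes

def make_mtec_bulk(n_genes: int = 2000, n_aire_dep: int = 100,
                   lfc_effect: float = -4.0, n_ko: int = 4, n_he: int = 4,
                   noise_sd: float = 0.25, seed: int = 0,
                   baseline_range: tuple[float, float] = (6.0, 12.0)
                   ) -> tuple[ExpressionMatrix, TruthRecord]:
    """Log2-scale KO-vs-control bulk matrix with planted Aire-dependent genes.

    Null genes share a common per-gene mean across genotypes; the planted
    genes have their KO mean shifted by ``lfc_effect`` (negative means
    downregulated in the knockout). Gaussian noise with sd ``noise_sd``.
    """
    if n_ko < 2 or n_he < 2:
        raise ValueError("need >=2 replicates per genotype for a DE test")
    if n_aire_dep > n_genes:
        raise ValueError("n_aire_dep cannot exceed n_genes")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"KO_{i}" for i in range(n_ko)] + [f"HE_{i}" for i in range(n_he)]
    geno = ["KO"] * n_ko + ["HE"] * n_he

    base = rng.uniform(*baseline_range, size=n_genes)
    mean = np.tile(base[:, None], (1, n_ko + n_he))
    dep_idx = rng.choice(n_genes, size=n_aire_dep, replace=False)
    mean[dep_idx, :n_ko] += lfc_effect
    X = np.clip(mean + rng.normal(0.0, noise_sd, size=mean.shape), 0.0, None)

    values = pd.DataFrame(X, index=genes, columns=samples)
    meta = pd.DataFrame({"genotype": geno, "group": "mTEC",
                         "animal": samples}, index=samples)
    truth = TruthRecord(planted_aire_dep={genes[i]: float(lfc_effect) for i in dep_idx})
    return ExpressionMatrix(values, meta, scale="log2"), truth


# ---------------------------------------------------------------------------
# multi-cell-type, multi-animal single-cell counts with planted tonic-ISG effect

def make_sc_counts(cell_types: tuple[str, ...] = ("B", "Macrophage", "NK", "T"),
                   n_animals_per_genotype: int = 3, cells_per_animal: int = 200,
                   n_genes: int = 2000, n_isg: int = 100, frac_tonic: float = 0.5,
                   tonic_lfc: float = -2.0, libsize_mean: float = 5000.0,
                   nb_dispersion: float = 2.0, seed: int = 0,
                   support_frac: dict[str, float] | None = None
                   ) -> tuple[CountMatrix, GeneSet, TruthRecord]:
    """Negative-binomial UMI counts across cell types, animals and genotypes.

    Per-cell expected counts are library_size x gene_proportion x
    genotype_effect, where genotype_effect = 2**tonic_lfc for tonic-sensitive
    ISGs in KO cells and 1 otherwise; library sizes are log-normal around
    ``libsize_mean`` and counts are NB with size parameter ``nb_dispersion``
    (variance mu + mu^2/size). ``support_frac`` optionally restricts a cell
    type's expressed-gene support to a fraction of the genes, which plants a
    richness difference for the diversity stage.

    Returns the count matrix, the ISG gene set with ``tonic_sensitive``
    labels, and the truth record.
    """
    if not cell_types:
        raise ValueError("need at least one cell type")
    if not 0 <= frac_tonic <= 1:
        raise ValueError("frac_tonic must be in [0, 1]")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if n_isg > n_genes:
        raise ValueError("n_isg cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    support_frac = support_frac or {}

    genes = [f"G{i:05d}" for i in range(n_genes)]
    isg_idx = np.arange(n_isg)
    n_tonic = int(round(frac_tonic * n_isg))
    tonic_idx = isg_idx[:n_tonic]

    # base gene proportions, mildly skewed as in real libraries
    base_w = rng.lognormal(0.0, 1.0, size=n_genes)

    # per-cell-type support restriction (genes outside the support never fire);
    # ISGs are kept inside every support so the IFN stages see all cell types
    type_w: dict[str, np.ndarray] = {}
    for ct in cell_types:
        w = base_w.copy()
        frac = support_frac.get(ct, 1.0)
        if frac < 1.0:
            n_keep = max(int(round(frac * n_genes)), n_isg)
            silenced = rng.choice(np.setdiff1d(np.arange(n_genes), isg_idx),
                                  size=n_genes - n_keep, replace=False)
            w[silenced] = 0.0
        type_w[ct] = w / w.sum()

    rows, cell_ids, meta_rows = [], [], []
    for genotype in ("KO", "HE"):
        effect = np.ones(n_genes)
        if genotype == "KO":
            effect[tonic_idx] = 2.0 ** tonic_lfc
        for a in range(n_animals_per_genotype):
            animal = f"{genotype}_rat{a}"
            for ct in cell_types:
                mu_gene = type_w[ct] * effect
                lib = rng.lognormal(np.log(libsize_mean), 0.3, size=cells_per_animal)
                mu = lib[:, None] * mu_gene[None, :]
                p = nb_dispersion / (nb_dispersion + mu)
                block = np.where(mu > 0,
                                 rng.negative_binomial(nb_dispersion, np.clip(p, 1e-12, 1.0)),
                                 0)
                rows.append(block)
                for c in range(cells_per_animal):
                    cell_ids.append(f"{animal}|{ct}|c{c:04d}")
                    meta_rows.append((ct, genotype, animal))

    counts = np.vstack(rows).astype(np.int64)
    meta = pd.DataFrame(meta_rows, columns=["cell_type", "genotype", "animal"],
                        index=cell_ids)
    labels = {genes[i]: bool(i in set(tonic_idx)) for i in isg_idx}
    isg_set = GeneSet("ISG", [genes[i] for i in isg_idx], labels)
    truth = TruthRecord(planted_isg={
        genes[i]: {"tonic_sensitive": bool(i in set(tonic_idx)),
                   "lfc": float(tonic_lfc) if i in set(tonic_idx) else 0.0}
        for i in isg_idx})
    return CountMatrix(counts, genes, cell_ids, meta), isg_set, truth


def make_tonic_reference(isg_set: GeneSet, truth: TruthRecord, n_genes_extra: int = 400,
                         lfc_effect: float = -3.0, n_per_group: int = 4,
                         noise_sd: float = 0.25, seed: int = 0) -> DETable:
    """Baseline interferon-receptor-knockout reference DE table.

    Simulates an unstimulated receptor-KO vs wild-type bulk contrast in which
    the truly tonic-sensitive ISGs (per the truth record) are downregulated
    by ``lfc_effect`` and everything else is null, then runs the package's
    own Welch-t DE test on it. Used to classify tonic sensitivity the same
    way the real pipeline would from published receptor-knockout data.
    """
    from .de import de_test

    rng = np.random.default_rng(seed)
    tonic_genes = [g for g, rec in truth.planted_isg.items() if rec["tonic_sensitive"]]
    genes = list(isg_set.genes) + [f"REF{i:04d}" for i in range(n_genes_extra)]
    samples = [f"refKO_{i}" for i in range(n_per_group)] + \
              [f"refWT_{i}" for i in range(n_per_group)]
    base = rng.uniform(6.0, 12.0, size=len(genes))
    mean = np.tile(base[:, None], (1, 2 * n_per_group))
    tonic_rows = [i for i, g in enumerate(genes) if g in set(tonic_genes)]
    mean[tonic_rows, :n_per_group] += lfc_effect
    X = np.clip(mean + rng.normal(0.0, noise_sd, size=mean.shape), 0.0, None)
    values = pd.DataFrame(X, index=genes, columns=samples)
    meta = pd.DataFrame({"genotype": ["KO"] * n_per_group + ["WT"] * n_per_group,
                         "group": "spleen", "animal": samples}, index=samples)
    return de_test(ExpressionMatrix(values, meta, scale="log2"), ko="KO", control="WT")


# ---------------------------------------------------------------------------
# paired rat/mouse DE tables with a planted conserved module

@dataclass
class CrossSpeciesData:
    rat_de: DETable
    mouse_des: dict[str, DETable]           # keyed by dataset name, mouse gene ids
    ortholog_map: pd.DataFrame              # columns rat_gene, mouse_gene
    tra_set: GeneSet                        # rat ids
    isg_set: GeneSet                        # rat ids
    sample_expr: pd.DataFrame               # samples x rat genes (for PCA)
    sample_meta: pd.DataFrame
    truth: TruthRecord = field(default_factory=TruthRecord)


def make_cross_species(n_genes: int = 1200, n_datasets_mouse: int = 4,
                       n_modules: int = 4, module_size: int = 50,
                       conserved_module_frac_tra: float = 0.5,
                       background_frac_tra: float = 0.1,
                       conserved_module_frac_isg: float = 0.3,
                       background_frac_isg: float = 0.05,
                       effect: float = -3.0, noise_sd: float = 0.4,
                       seed: int = 0) -> CrossSpeciesData:
    """Rat + mouse knockout DE tables over one-to-one orthologs with planted modules.

    Module 1 is conserved: downregulated in the knockout in every dataset.
    The remaining modules are species- or dataset-specific (distinct dataset
    subsets). The conserved module is seeded with TRA and ISG membership at a
    higher rate than background, so module enrichment has a planted positive
    signal. DE p values are constructed from the per-gene effect-to-noise
    ratio and BH-adjusted, matching what a well-powered two-group test would
    report.
    """
    if n_modules < 2:
        raise ValueError("need at least 2 modules")
    if n_modules * module_size > n_genes:
        raise ValueError("modules do not fit into n_genes")
    rng = np.random.default_rng(seed)

    rat_genes = [f"Rg{i:05d}" for i in range(n_genes)]
    mouse_genes = [f"Mg{i:05d}" for i in range(n_genes)]
    omap = pd.DataFrame({"rat_gene": rat_genes, "mouse_gene": mouse_genes,
                         "provenance": "synthetic"})

    datasets = ["rat"] + [f"mouse_{i+1}" for i in range(n_datasets_mouse)]
    n_ds = len(datasets)

    # dataset pattern per module: module 1 hits every dataset, the others hit
    # distinct proper subsets (rat-only, mouse-only, alternating mouse halves...)
    patterns = [np.ones(n_ds, dtype=bool)]
    candidates = [np.eye(n_ds, dtype=bool)[0],                       # rat only
                  ~np.eye(n_ds, dtype=bool)[0],                      # all mouse
                  np.array([False] + [i < n_datasets_mouse // 2
                                      for i in range(n_datasets_mouse)]),
                  np.array([False] + [i >= n_datasets_mouse // 2
                                      for i in range(n_datasets_mouse)])]
    for c in candidates:
        if len(patterns) < n_modules and c.any() and not any((c == p).all() for p in patterns):
            patterns.append(c)
    while len(patterns) < n_modules:  # fall back to random distinct subsets
        c = rng.random(n_ds) < 0.5
        if c.any() and not c.all() and not any((c == p).all() for p in patterns):
            patterns.append(c)

    module_of = np.zeros(n_genes, dtype=int)
    order = rng.permutation(n_genes)
    for m in range(n_modules):
        module_of[order[m * module_size:(m + 1) * module_size]] = m + 1

    lfc = rng.normal(0.0, noise_sd, size=(n_genes, n_ds))
    for m in range(1, n_modules + 1):
        rows = module_of == m
        lfc[np.ix_(rows, patterns[m - 1])] += effect

    def build_de(col: int, ids: list[str]) -> DETable:
        z = np.abs(lfc[:, col]) / noise_sd
        p = np.clip(2 * st.norm.sf(z), 1e-300, 1.0)
        return DETable(pd.DataFrame({"lfc": lfc[:, col], "p": p, "padj": adjust_bh(p)},
                                    index=pd.Index(ids, name="gene")))

    rat_de = build_de(0, rat_genes)
    mouse_des = {ds: build_de(i + 1, mouse_genes) for i, ds in enumerate(datasets[1:])}

    conserved = module_of == 1
    r_tra, r_isg = rng.random(n_genes), rng.random(n_genes)
    tra_mask = np.where(conserved, r_tra < conserved_module_frac_tra,
                        r_tra < background_frac_tra)
    isg_mask = np.where(conserved, r_isg < conserved_module_frac_isg,
                        r_isg < background_frac_isg)
    tra_set = GeneSet("TRA", [g for g, m in zip(rat_genes, tra_mask) if m])
    isg_set = GeneSet("ISG", [g for g, m in zip(rat_genes, isg_mask) if m])

    # sample-level expression over module genes for PCA: per dataset, 2 KO + 2
    # Aire-sufficient samples; KO samples carry the dataset's module effects
    mod_rows = module_of > 0
    mod_genes = [g for g, m in zip(rat_genes, mod_rows) if m]
    base = rng.uniform(6.0, 12.0, size=mod_rows.sum())
    sample_rows, sample_ids, sample_meta_rows = [], [], []
    for d, ds in enumerate(datasets):
        for geno, shift in (("KO", 1.0), ("WT", 0.0)):
            for r in range(2):
                prof = base + shift * lfc[mod_rows, d] \
                    + rng.normal(0.0, noise_sd / 2, size=mod_rows.sum())
                sample_rows.append(prof)
                sample_ids.append(f"{ds}_{geno}_{r}")
                sample_meta_rows.append((ds, geno))
    sample_expr = pd.DataFrame(sample_rows, index=sample_ids, columns=mod_genes)
    sample_meta = pd.DataFrame(sample_meta_rows, columns=["dataset", "genotype"],
                               index=sample_ids)

    truth = TruthRecord(planted_modules={rat_genes[i]: int(module_of[i])
                                         for i in range(n_genes) if module_of[i] > 0})
    return CrossSpeciesData(rat_de, mouse_des, omap, tra_set, isg_set,
                            sample_expr, sample_meta, truth)
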