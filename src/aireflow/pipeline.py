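"""Stage orchestration: every analysis stage as a file-in/file-out step.

Stages run in a fixed order (simulate -> tra-call -> de -> enrich -> gsea ->
ifn-score -> diversity -> cross-species); each reads only files earlier
stages wrote under the run directory, so the CLI subcommands can also be run
standalone on each other's outputs. Every output file carries the config
hash and seed in a '#' header comment, and each stage writes a small JSON
summary. Deterministic stages are byte-identical under rerun with the same
config; stochastic stages draw from a generator derived from (seed, stage
name).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossspecies as xs
from . import de as de_mod
from . import diversity as div
from . import enrich, ifn, io, simulate, tra
from .config import PipelineConfig
from .containers import DETable, GeneSet

log = logging.getLogger(__name__)

STAGES = ("simulate", "tra-call", "de", "enrich", "gsea",
          "ifn-score", "diversity", "cross-species")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and original cause."""


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order under ``config.out_dir``."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        try:
            RUNNERS[stage](config, run_dir)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return run_dir


def _summary(config: PipelineConfig, run_dir: Path, stage: str, payload: dict) -> None:
    out = {"stage": stage, "seed": config.seed, "config_hash": config.config_hash(),
           **payload}
    (run_dir / f"{stage}.json").write_text(json.dumps(out, indent=2, default=float) + "\n")


def _write_de(de: DETable, path: Path, header: str) -> None:
    io.write_table(de.table, path, header=header)


def _read_de(path: Path) -> DETable:
    return DETable(io.read_table(path))


# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, run_dir: Path) -> None:
    """Generate every synthetic input with planted ground truth."""
    d = run_dir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    hdr = config.output_header("simulate")
    sim = dict(config.simulate)
    rng_seed = config.stage_rng("simulate").integers(2**31)

    panel, truth_tra = simulate.make_tissue_panel(
        seed=int(rng_seed), **sim.get("tissue_panel", {}))
    io.write_expression(panel, d / "tissue_panel.tsv", d / "tissue_meta.tsv", header=hdr)

    bulk, truth_bulk = simulate.make_mtec_bulk(
        seed=int(rng_seed) + 1, **sim.get("mtec_bulk", {}))
    io.write_expression(bulk, d / "mtec_bulk.tsv", d / "mtec_meta.tsv", header=hdr)

    sc_kwargs = dict(sim.get("sc_counts", {}))
    sc_kwargs.setdefault("support_frac", {"T": 0.5})
    counts, isg_set, truth_sc = simulate.make_sc_counts(seed=int(rng_seed) + 2, **sc_kwargs)
    io.write_count_matrix(counts, d / "sc", d / "sc_meta.tsv")
    io.write_gmt([isg_set], d / "isg.gmt")
    tonic_truth = [g for g, r in truth_sc.planted_isg.items() if r["tonic_sensitive"]]
    io.write_gmt([GeneSet("tonic_truth", tonic_truth)], d / "tonic_truth.gmt")

    ref_de = simulate.make_tonic_reference(isg_set, truth_sc, seed=int(rng_seed) + 3,
                                           **sim.get("tonic_reference", {}))
    _write_de(ref_de, d / "tonic_reference_de.tsv", hdr)

    cs = simulate.make_cross_species(seed=int(rng_seed) + 4, **sim.get("cross_species", {}))
    _write_de(cs.rat_de, d / "cs_rat_de.tsv", hdr)
    for name, de in cs.mouse_des.items():
        _write_de(de, d / f"cs_{name}_de.tsv", hdr)
    io.write_table(cs.ortholog_map.set_index("rat_gene"), d / "ortholog_map.tsv", header=hdr)
    io.write_gmt([cs.tra_set, cs.isg_set], d / "cs_sets.gmt")
    io.write_table(cs.sample_expr.rename_axis("sample"), d / "cs_sample_expr.tsv", header=hdr)
    io.write_table(cs.sample_meta.rename_axis("sample"), d / "cs_sample_meta.tsv", header=hdr)

    truth = {"planted_tra": truth_tra.planted_tra,
             "planted_aire_dep": truth_bulk.planted_aire_dep,
             "planted_isg": truth_sc.planted_isg,
             "planted_modules": cs.truth.planted_modules,
             "mouse_datasets": sorted(cs.mouse_des)}
    (d / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    _summary(config, run_dir, "simulate", {
        "n_tissue_samples": len(panel.sample_ids), "n_cells": counts.n_cells,
        "n_planted_tra": len(truth_tra.planted_tra)})


def stage_tra_call(config: PipelineConfig, run_dir: Path) -> None:
    """Group reduction and dynamic-step TRA calling on the tissue panel."""
    d = run_dir / "simulate"
    hdr = config.output_header("tra-call")
    panel = io.read_expression(d / "tissue_panel.tsv", d / "tissue_meta.tsv", scale="linear")
    assignment, group_means = tra.reduce_to_groups(panel, n_groups=config.tra.n_groups)
    calls = tra.call_tra(group_means, j_max=config.tra.j_max,
                         form=config.tra.threshold_form)
    out = run_dir / "tra"
    io.write_table(assignment.to_frame().rename_axis("sample"),
                   out / "group_assignment.tsv", header=hdr)
    io.write_table(calls, out / "tra_calls.tsv", header=hdr)
    _summary(config, run_dir, "tra-call", {
        "n_groups": config.tra.n_groups, "threshold_form": config.tra.threshold_form,
        "n_called": int(calls["is_tra"].sum())})


def stage_de(config: PipelineConfig, run_dir: Path) -> None:
    """Bulk mTEC DE (Aire-dependent definition) and per-population pseudobulk DE."""
    d = run_dir / "simulate"
    hdr = config.output_header("de")
    out = run_dir / "de"

    bulk = io.read_expression(d / "mtec_bulk.tsv", d / "mtec_meta.tsv", scale="log2")
    mtec_de = de_mod.de_test(bulk)
    _write_de(mtec_de, out / "mtec_de.tsv", hdr)
    aire_dep = de_mod.define_aire_dependent(
        mtec_de, lfc_cut=config.thresholds.lfc_cut, fdr_cut=config.thresholds.fdr_cut)
    io.write_gmt([aire_dep], out / "aire_dependent.gmt")

    counts = io.read_count_matrix(d / "sc", d / "sc_meta.tsv")
    pb = de_mod.pseudobulk(counts)
    io.write_table(pb.sums.rename_axis("stratum"), out / "pseudobulk_sums.tsv", header=hdr)
    io.write_table(pb.meta.rename_axis("stratum"), out / "pseudobulk_meta.tsv", header=hdr)
    pops = de_mod.de_by_population(pb)
    for ct, de in pops.items():
        _write_de(de, out / f"de_{ct}.tsv", hdr)
    _summary(config, run_dir, "de", {
        "n_aire_dependent": len(aire_dep.genes), "populations": sorted(pops)})


def _population_de_tables(run_dir: Path) -> dict[str, DETable]:
    meta = io.read_table(run_dir / "de" / "pseudobulk_meta.tsv")
    tables = {}
    for ct in sorted(meta["cell_type"].unique()):
        path = run_dir / "de" / f"de_{ct}.tsv"
        if path.exists():
            tables[ct] = _read_de(path)
    return tables


def stage_enrich(config: PipelineConfig, run_dir: Path) -> None:
    """ISG enrichment among downregulated genes, per population, Holm-adjusted."""
    hdr = config.output_header("enrich")
    isg_set = io.read_gmt(run_dir / "simulate" / "isg.gmt")[0]
    pops = _population_de_tables(run_dir)
    results = enrich.enrichment_by_population(
        pops, isg_set, lfc_cut=config.thresholds.lfc_cut, fdr_cut=config.thresholds.fdr_cut)
    io.write_table(enrich.enrichment_table(results),
                   run_dir / "enrich" / "isg_by_population.tsv", header=hdr)
    _summary(config, run_dir, "enrich", {
        "min_holm_p": float(np.nanmin([r.adjusted_p for r in results])),
        "all_or_above_1": bool(all(r.odds_ratio > 1 for r in results if np.isfinite(r.odds_ratio)))})


def stage_gsea(config: PipelineConfig, run_dir: Path) -> None:
    """Downsampled pre-ranked GSEA of the ISG and Aire-dependent sets.

    The ranking statistic is the log2 fold change of an animal-level
    pseudobulk KO-vs-control contrast pooled over all cell types of the
    single-cell cohort.
    """
    hdr = config.output_header("gsea")
    rng = config.stage_rng("gsea")
    d = run_dir / "simulate"

    counts = io.read_count_matrix(d / "sc", d / "sc_meta.tsv")
    pooled_meta = counts.cell_meta.copy()
    pooled_meta["cell_type"] = "all"
    counts_pooled = type(counts)(counts.counts, counts.gene_ids, counts.cell_ids, pooled_meta)
    pb = de_mod.pseudobulk(counts_pooled)
    pooled_de = de_mod.de_test(pb.expression_for("all"))
    ranked = pooled_de.table["lfc"].sort_values(ascending=False)

    sets = [io.read_gmt(d / "isg.gmt")[0]]
    aire_path = run_dir / "de" / "aire_dependent.gmt"
    if aire_path.exists():
        aire = io.read_gmt(aire_path)[0]
        aire = aire.intersect(ranked.index)
        if len(aire) >= 2:
            sets.append(aire)
    sets = [s.intersect(ranked.index) for s in sets]
    sets = enrich.downsample_sets([s for s in sets if len(s) >= 2], rng)

    rows = []
    for s in sets:
        res = enrich.gsea_preranked(ranked, s, weight=config.gsea.weight,
                                    n_perm=config.gsea.n_perm, rng=rng)
        rows.append({"set": s.name, "ES": res.es, "NES": res.nes, "p_perm": res.p_perm,
                     "set_size": res.set_size, "n_perm": res.n_perm,
                     "leading_edge_size": len(res.leading_edge)})
        io.write_table(res.running_sum.to_frame().rename_axis("gene"),
                       run_dir / "gsea" / f"running_{s.name}.tsv", header=hdr)
    io.write_table(pd.DataFrame(rows).set_index("set"),
                   run_dir / "gsea" / "gsea.tsv", header=hdr)
    _summary(config, run_dir, "gsea", {"results": rows})


def stage_ifn_score(config: PipelineConfig, run_dir: Path) -> None:
    """Tonic-sensitivity classification and per-cell-type IFN scores."""
    hdr = config.output_header("ifn-score")
    d = run_dir / "simulate"
    isg_set = io.read_gmt(d / "isg.gmt")[0]
    ref_de = _read_de(d / "tonic_reference_de.tsv")
    tonic = ifn.classify_tonic(ref_de, isg_set, lfc_cut=config.thresholds.lfc_cut,
                               fdr_cut=config.thresholds.fdr_cut)
    io.write_table(tonic.table, run_dir / "ifn" / "tonic_labels.tsv", header=hdr)

    counts = io.read_count_matrix(d / "sc", d / "sc_meta.tsv")
    pb = de_mod.pseudobulk(counts)
    per_animal = {ct: pb.expression_for(ct)
                  for ct in sorted(pb.meta["cell_type"].unique())}
    scores = ifn.ifn_score_by_cell_type(per_animal, tonic)
    io.write_table(scores.set_index("animal"), run_dir / "ifn" / "ifn_scores.tsv", header=hdr)
    _summary(config, run_dir, "ifn-score", {
        "n_tonic": len(tonic.tonic_genes),
        "mean_score": float(scores["score"].mean()),
        "all_negative": bool((scores["score"] < 0).all())})


def stage_diversity(config: PipelineConfig, run_dir: Path) -> None:
    """Hill-number (q=0) rarefaction/extrapolation and Wald comparisons."""
    hdr = config.output_header("diversity")
    rng = config.stage_rng("diversity")
    d = run_dir / "simulate"
    counts = io.read_count_matrix(d / "sc", d / "sc_meta.tsv")
    pops = sorted(counts.cell_meta["cell_type"].unique())

    totals = {p: int(div.pooled_abundance(counts, p).sum()) for p in pops}
    m_star = int(config.diversity.extrapolation_factor * min(totals.values()))
    grid = np.unique(np.geomspace(10, m_star, 12).astype(int))

    results = [div.population_curve(counts, p, grid, n_boot=config.diversity.n_boot,
                                    rng=rng) for p in pops]
    curves = pd.concat([r.curve.assign(population=r.population) for r in results])
    io.write_table(curves.set_index("population"), run_dir / "diversity" / "curves.tsv",
                   header=hdr)
    reference = pops[0]
    comp = div.compare_to_reference(results, reference, m_star)
    io.write_table(comp, run_dir / "diversity" / "comparison.tsv", header=hdr)
    _summary(config, run_dir, "diversity", {
        "reference": reference, "m_star": m_star,
        "s_obs": {r.population: r.s_obs for r in results},
        "chao1": {r.population: r.chao1 for r in results}})


def stage_cross_species(config: PipelineConfig, run_dir: Path) -> None:
    """Ortholog combination, gene modules, module enrichment, PCA, clustering."""
    hdr = config.output_header("cross-species")
    rng = config.stage_rng("cross-species")
    d = run_dir / "simulate"
    out = run_dir / "cross_species"

    rat_de = _read_de(d / "cs_rat_de.tsv")
    truth = json.loads((d / "truth.json").read_text())
    mouse_des = {name: _read_de(d / f"cs_{name}_de.tsv")
                 for name in truth["mouse_datasets"]}
    omap = io.read_ortholog_map(d / "ortholog_map.tsv")
    omap = xs.filter_one_to_one(omap)
    combined = xs.combine_orthologs(rat_de, mouse_des, omap)

    # Aire-regulated = significant in at least one dataset
    sig = np.zeros(len(combined), dtype=bool)
    lfc_cut, fdr_cut = config.thresholds.lfc_cut, config.thresholds.fdr_cut
    for name, de in [("rat", rat_de)] + list(mouse_des.items()):
        t = de.table
        hits = set(t.index[(t["lfc"] < lfc_cut) & (t["padj"] < fdr_cut)])
        if name != "rat":
            m2r = dict(zip(omap["mouse_gene"], omap["rat_gene"]))
            hits = {m2r.get(g, g) for g in hits}
        sig |= combined.index.isin(hits)
    regulated = combined[sig]

    assignment = xs.kmeans_modules(regulated, k=4, rng=rng)
    io.write_table(assignment.modules.to_frame().join(regulated),
                   out / "modules.tsv", header=hdr)

    sets = {s.name: s for s in io.read_gmt(d / "cs_sets.gmt")}
    enr_frames = []
    for name, s in sorted(sets.items()):
        res = xs.module_set_enrichment(assignment, s)
        frame = enrich.enrichment_table(res)
        frame.insert(0, "set", name)
        enr_frames.append(frame)
    io.write_table(pd.concat(enr_frames), out / "module_enrichment.tsv", header=hdr)

    sample_expr = io.read_table(d / "cs_sample_expr.tsv")
    coords, varexp = xs.pca_samples(sample_expr)
    coords["varexp_pc1"] = varexp[0]
    io.write_table(coords.rename_axis("sample"), out / "pca.tsv", header=hdr)

    counts = io.read_count_matrix(d / "sc", d / "sc_meta.tsv")
    X = counts.lognorm()
    mean_expr = pd.DataFrame(X, index=counts.cell_ids, columns=counts.gene_ids) \
        .groupby(counts.cell_meta["cell_type"].to_numpy()).mean()
    dend = xs.cluster_populations(mean_expr, n_boot=min(200, 1000), rng=rng)
    (out / "dendrogram.nwk").parent.mkdir(parents=True, exist_ok=True)
    (out / "dendrogram.nwk").write_text(dend.newick() + "\n")

    isg_genes = [g for g in sets["ISG"].genes if g in combined.index]
    sp_rows = []
    for name in mouse_des:
        pair = combined[["rat", name]].loc[isg_genes].dropna()
        if len(pair) >= 5:
            rho, p = xs.spearman_compare(pair["rat"], pair[name])
            sp_rows.append({"dataset": name, "rho": rho, "p": p, "n": len(pair)})
    io.write_table(pd.DataFrame(sp_rows).set_index("dataset"),
                   out / "spearman.tsv", header=hdr)

    mod_or = {r.population: r.odds_ratio
              for r in xs.module_set_enrichment(assignment, sets["TRA"])}
    _summary(config, run_dir, "cross-species", {
        "n_regulated": int(len(regulated)),
        "module_sizes": assignment.modules.value_counts().sort_index().to_dict(),
        "tra_or_by_module": mod_or})


RUNNERS = {
    "simulate": stage_simulate,
    "tra-call": stage_tra_call,
    "de": stage_de,
    "enrich": stage_enrich,
    "gsea": stage_gsea,
    "ifn-score": stage_ifn_score,
    "diversity": stage_diversity,
    "cross-species": stage_cross_species,
}
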