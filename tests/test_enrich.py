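"""Fisher over-representation, downsampled pre-ranked GSEA, module scores."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from aireflow import enrich, simulate
from aireflow.containers import GeneSet


def _hypergeom_tail_brute(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c), by enumeration."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = comb(N, n)
    return sum(comb(K, k) * comb(N - K, n - k)
               for k in range(a, min(K, n) + 1)) / denom


def _build_universe(a, b, c, d):
    universe = [f"u{i}" for i in range(a + b + c + d)]
    in_set = universe[: a + b]
    hits = universe[:a] + universe[a + b: a + b + c]
    return universe, hits, GeneSet("S", in_set)


class TestFisherEnrichment:
    def test_balanced_table(self):
        universe, hits, s = _build_universe(10, 10, 10, 10)
        res = enrich.fisher_enrichment(universe, hits, s)
        assert res.odds_ratio == pytest.approx(1.0)
        # exact enumeration: P(X >= 10) = (1 + P(X = 10)) / 2 for the symmetric table
        assert res.p == pytest.approx(_hypergeom_tail_brute(10, 10, 10, 10))
        assert res.p == pytest.approx(0.6238, abs=0.001)

    def test_strong_enrichment_exact_tail(self):
        universe, hits, s = _build_universe(9, 1, 1, 9)
        res = enrich.fisher_enrichment(universe, hits, s)
        assert res.odds_ratio == pytest.approx(81.0)
        assert res.p == pytest.approx(101 / 184756)

    def test_disjoint_set_degenerate(self):
        res = enrich.fisher_enrichment(["x", "y"], ["x"], GeneSet("S", ["z"]))
        assert res.a == 0 and res.b == 0
        assert "degenerate" in res.flags
        assert res.p == 1.0

    def test_zero_cell_gets_haldane_correction(self):
        universe, hits, s = _build_universe(5, 0, 3, 7)
        res = enrich.fisher_enrichment(universe, hits, s)
        assert "haldane" in res.flags
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_oracle_equivalence_small_tables(self, rng):
        """Exact tail p matches brute-force enumeration for all table shapes
        up to universe size 60."""
        for _ in range(300):
            N = int(rng.integers(4, 61))
            a = int(rng.integers(0, N + 1))
            b = int(rng.integers(0, N - a + 1))
            c = int(rng.integers(0, N - a - b + 1))
            d = N - a - b - c
            if a + b == 0:
                continue
            universe, hits, s = _build_universe(a, b, c, d)
            res = enrich.fisher_enrichment(universe, hits, s)
            assert res.p == pytest.approx(_hypergeom_tail_brute(a, b, c, d), abs=1e-12)


class TestEnrichmentByPopulation:
    def test_single_population_holm_equals_raw(self):
        t = pd.DataFrame({"lfc": [-3, -2, 0, 0.5], "p": [1e-5, 1e-4, 0.5, 0.9],
                          "padj": [4e-5, 2e-4, 0.6, 0.9]},
                         index=["i1", "i2", "n1", "n2"])
        res = enrich.enrichment_by_population(
            {"B": enrich.DETable(t)}, GeneSet("ISG", ["i1", "i2"]))
        assert res[0].adjusted_p == pytest.approx(res[0].p)

    def test_planted_downregulation_detected_in_every_population(self):
        counts, isg, _ = simulate.make_sc_counts(
            cell_types=("B", "NK"), n_animals_per_genotype=3, cells_per_animal=100,
            n_genes=600, n_isg=60, tonic_lfc=-2.0, seed=9)
        from aireflow.de import de_by_population, pseudobulk
        pops = de_by_population(pseudobulk(counts))
        res = enrich.enrichment_by_population(pops, isg)
        assert all(r.odds_ratio > 1 for r in res)
        assert min(r.adjusted_p for r in res) < 0.05


class TestDownsampleSets:
    def test_subset_property_and_min_set_untouched(self, rng):
        big = GeneSet("big", [f"g{i}" for i in range(50)])
        small = GeneSet("small", [f"h{i}" for i in range(10)])
        out = enrich.downsample_sets([big, small], rng)
        assert len(out[0]) == len(out[1]) == 10
        assert set(out[0].genes) <= set(big.genes)
        assert out[1].genes == small.genes

    def test_deterministic_given_seed(self):
        big = GeneSet("big", [f"g{i}" for i in range(50)])
        small = GeneSet("small", [f"h{i}" for i in range(10)])
        a = enrich.downsample_sets([big, small], np.random.default_rng(4))
        b = enrich.downsample_sets([big, small], np.random.default_rng(4))
        assert a[0].genes == b[0].genes


class TestGseaPreranked:
    def _ranked(self, stats, n=None):
        n = n or len(stats)
        return pd.Series(stats, index=[f"g{i}" for i in range(n)], dtype=float)

    def test_single_top_gene_hits_es_one(self, rng):
        ranked = self._ranked(np.linspace(5, 0.1, 20))
        res = enrich.gsea_preranked(ranked, GeneSet("S", ["g0"]), n_perm=50, rng=rng)
        assert res.es == pytest.approx(1.0)
        assert res.running_sum.iloc[0] == pytest.approx(1.0)
        assert res.leading_edge == ["g0"]

    def test_es_bounded_and_reversal_negates(self, rng):
        stats = rng.normal(size=60)
        ranked = self._ranked(stats)
        s = GeneSet("S", [f"g{i}" for i in rng.choice(60, 10, replace=False)])
        res = enrich.gsea_preranked(ranked, s, n_perm=100, rng=np.random.default_rng(0))
        assert -1 <= res.es <= 1
        rev = enrich.gsea_preranked(-ranked, s, n_perm=100, rng=np.random.default_rng(0))
        assert rev.es == pytest.approx(-res.es)

    def test_null_symmetry_with_flat_statistics(self):
        """With exchangeable set membership the ES distribution is centred at 0."""
        es = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            stats = rng.normal(0, 1, size=30)
            ranked = self._ranked(stats)
            s = GeneSet("S", [f"g{i}" for i in rng.choice(30, 5, replace=False)])
            es.append(enrich.gsea_preranked(ranked, s, n_perm=1, rng=rng).es)
        se = np.std(es) / np.sqrt(len(es))
        assert abs(np.mean(es)) < 3 * se + 0.02

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """6-gene list, 3-gene set: permutation p within 3 MC SD of the exact
        p over all C(6,3)=20 membership assignments."""
        ranked = self._ranked([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        s = GeneSet("S", ["g0", "g1", "g2"])
        n_perm = 4000
        res = enrich.gsea_preranked(ranked, s, n_perm=n_perm,
                                    rng=np.random.default_rng(123))

        stats = ranked.to_numpy()

        def es_of(mask):
            w = np.abs(stats) * mask
            steps = w / w.sum() - (~mask) / (~mask).sum()
            rs = np.cumsum(steps)
            return rs[np.argmax(np.abs(rs))]

        null = [es_of(np.isin(np.arange(6), idx))
                for idx in itertools.combinations(range(6), 3)]
        null = np.array(null)
        same = null >= 0 if res.es >= 0 else null < 0
        exact = (np.abs(null[same]) >= abs(res.es) - 1e-12).sum() / same.sum()
        mc_sd = np.sqrt(exact * (1 - exact) / n_perm) if 0 < exact < 1 else 1 / n_perm
        assert abs(res.p_perm - exact) <= 3 * mc_sd + 2 / n_perm

    def test_full_coverage_rejected(self, rng):
        ranked = self._ranked([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="entire"):
            enrich.gsea_preranked(ranked, GeneSet("S", ["g0", "g1", "g2"]), rng=rng)


class TestModuleScore:
    def test_null_centering_and_determinism(self):
        counts, _, _ = simulate.make_sc_counts(
            cell_types=("B",), n_animals_per_genotype=2, cells_per_animal=150,
            n_genes=500, n_isg=0, tonic_lfc=0.0, seed=2)
        rng = np.random.default_rng(0)
        s = GeneSet("S", [f"G{i:05d}" for i in range(40, 80)])
        score = enrich.module_score(counts, s, rng=np.random.default_rng(7))
        again = enrich.module_score(counts, s, rng=np.random.default_rng(7))
        pd.testing.assert_series_equal(score, again)
        se = score.std() / np.sqrt(len(score))
        assert abs(score.mean()) < 3 * se + 0.01

    def test_planted_subpopulation_scores_higher(self):
        import scipy.stats as st
        counts, isg, _ = simulate.make_sc_counts(
            cell_types=("B", "NK"), n_animals_per_genotype=2, cells_per_animal=150,
            n_genes=500, n_isg=40, tonic_lfc=-2.0, seed=6)
        tonic = GeneSet("tonic", [g for g, v in isg.labels.items() if v])
        score = enrich.module_score(counts, tonic, rng=np.random.default_rng(1))
        ko = counts.cell_meta["genotype"] == "KO"
        # tonic genes are DOWN in KO cells: KO scores below control scores
        stat = st.mannwhitneyu(score[ko.to_numpy()], score[(~ko).to_numpy()],
                               alternative="less")
        assert stat.pvalue < 0.01
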