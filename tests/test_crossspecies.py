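"""Cross-species combination, gene modules, PCA, population clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from aireflow import crossspecies as xs
from aireflow import simulate
from aireflow.containers import DETable, GeneSet


def _de(genes, lfc):
    lfc = np.asarray(lfc, dtype=float)
    p = np.full(len(genes), 0.5)
    return DETable(pd.DataFrame({"lfc": lfc, "p": p, "padj": p}, index=genes))


class TestCombineOrthologs:
    def test_identity_map_gives_equal_columns(self):
        genes = ["r1", "r2", "r3"]
        omap = pd.DataFrame({"rat_gene": genes, "mouse_gene": genes})
        combined = xs.combine_orthologs(_de(genes, [1, -2, 0.5]),
                                        {"m": _de(genes, [1, -2, 0.5])}, omap)
        np.testing.assert_allclose(combined["rat"], combined["m"])

    def test_missing_gene_absent_in_one_column_only(self):
        omap = pd.DataFrame({"rat_gene": ["r1", "r2"], "mouse_gene": ["m1", "m2"]})
        combined = xs.combine_orthologs(
            _de(["r1", "r2"], [1, 2]),
            {"a": _de(["m1"], [3]), "b": _de(["m1", "m2"], [4, 5])}, omap)
        assert np.isnan(combined.loc["r2", "a"])
        assert combined.loc["r2", "b"] == 5

    def test_many_to_many_rejected_and_filterable(self):
        omap = pd.DataFrame({"rat_gene": ["r1", "r1"], "mouse_gene": ["m1", "m2"]})
        with pytest.raises(ValueError, match="one-to-one"):
            xs.combine_orthologs(_de(["r1"], [1]), {"a": _de(["m1"], [1])}, omap)
        filtered = xs.filter_one_to_one(omap)
        assert len(filtered) == 0  # ambiguous rat gene dropped entirely

    def test_conserved_module_present_in_all_columns(self):
        cs = simulate.make_cross_species(seed=3)
        combined = xs.combine_orthologs(cs.rat_de, cs.mouse_des,
                                        xs.filter_one_to_one(cs.ortholog_map))
        conserved = [g for g, m in cs.truth.planted_modules.items() if m == 1]
        assert combined.loc[conserved].notna().all().all()


class TestKmeansModules:
    def test_recovers_two_planted_modules(self):
        cs = simulate.make_cross_species(n_modules=2, effect=-4.0, noise_sd=0.3, seed=8)
        combined = xs.combine_orthologs(cs.rat_de, cs.mouse_des,
                                        xs.filter_one_to_one(cs.ortholog_map))
        genes = list(cs.truth.planted_modules)
        assignment = xs.kmeans_modules(combined.loc[genes], k=2,
                                       rng=np.random.default_rng(1))
        truth = [cs.truth.planted_modules[g] for g in genes]
        assert adjusted_rand_score(truth, assignment.modules[genes]) >= 0.9

    def test_deterministic_given_seed_and_k1(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)),
                         index=[f"g{i}" for i in range(30)])
        a = xs.kmeans_modules(X, k=3, rng=np.random.default_rng(5))
        b = xs.kmeans_modules(X, k=3, rng=np.random.default_rng(5))
        pd.testing.assert_series_equal(a.modules, b.modules)
        one = xs.kmeans_modules(X, k=1, rng=np.random.default_rng(5))
        assert (one.modules == 1).all()
        Z = (X - X.mean()) / X.std(ddof=0)
        assert one.wcss == pytest.approx(((Z - Z.mean()) ** 2).sum().sum())

    def test_k_too_large_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="k="):
            xs.kmeans_modules(X, k=4)


class TestModuleSetEnrichment:
    def test_planted_fifty_percent_module_or_near_nine(self, rng):
        """Module at 50% set membership vs 10% background: expected sample OR
        = (0.5/0.5)/(0.1/0.9) = 9."""
        ors = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(400)]
            modules = pd.Series([1] * 100 + [2] * 300, index=genes)
            in_set = np.concatenate([r.random(100) < 0.5, r.random(300) < 0.1])
            assignment = xs.ModuleAssignment(modules, 0.0,
                                             pd.Series(False, index=genes))
            s = GeneSet("S", [g for g, m in zip(genes, in_set) if m])
            res = xs.module_set_enrichment(assignment, s)
            ors.append(res[0].odds_ratio)
        assert np.median(ors) == pytest.approx(9.0, rel=0.25)

    def test_empty_set_degenerate_flag(self):
        genes = [f"g{i}" for i in range(10)]
        assignment = xs.ModuleAssignment(pd.Series([1] * 5 + [2] * 5, index=genes),
                                         0.0, pd.Series(False, index=genes))
        res = xs.module_set_enrichment(assignment, GeneSet("S", ["absent"]))
        assert all("degenerate" in r.flags for r in res)

    def test_uniform_set_null_across_modules(self):
        """A set spread uniformly over modules shows no significant module."""
        n_sig = 0
        for seed in range(60):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(300)]
            modules = pd.Series(r.integers(1, 4, size=300), index=genes)
            s = GeneSet("S", [g for g in genes if r.random() < 0.2])
            assignment = xs.ModuleAssignment(modules, 0.0,
                                             pd.Series(False, index=genes))
            res = xs.module_set_enrichment(assignment, s)
            n_sig += any(rr.adjusted_p < 0.05 for rr in res)
        assert n_sig / 60 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)


class TestPcaSamples:
    def test_duplicated_sample_identical_coordinates(self, rng):
        X = rng.normal(size=(5, 20))
        X[4] = X[0]
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(5)])
        coords, varexp = xs.pca_samples(df)
        np.testing.assert_allclose(coords.loc["s0"], coords.loc["s4"], atol=1e-8)
        assert (np.diff(varexp) <= 1e-12).all()
        assert varexp.sum() <= 1 + 1e-9

    def test_planted_groups_separate_on_pc1(self, rng):
        X = rng.normal(size=(12, 40))
        X[6:] += 8.0  # two well-separated sample groups
        coords, _ = xs.pca_samples(pd.DataFrame(X))
        labels = [0] * 6 + [1] * 6
        assert silhouette_score(coords[["PC1"]], labels) > 0.8

    def test_ordering_invariance_up_to_sign_convention(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 15)),
                         index=[f"s{i}" for i in range(8)],
                         columns=[f"g{i}" for i in range(15)])
        c1, _ = xs.pca_samples(X)
        perm = X.sample(frac=1, axis=1, random_state=3)  # shuffle genes
        c2, _ = xs.pca_samples(perm)
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-8)

    def test_all_zero_variance_rejected(self):
        X = pd.DataFrame(np.ones((4, 5)))
        with pytest.raises(ValueError, match="variance"):
            xs.pca_samples(X)


class TestClusterPopulations:
    def test_duplicate_profiles_get_full_support(self, rng):
        X = rng.normal(size=(4, 60))
        X[1] = X[0] + rng.normal(0, 1e-9, size=60)  # near-exact duplicate pair
        df = pd.DataFrame(X, index=["p0", "p1", "p2", "p3"])
        dend = xs.cluster_populations(df, n_boot=50, rng=np.random.default_rng(2))
        assert dend.support[frozenset({"p0", "p1"})] == pytest.approx(1.0)
        nwk = dend.newick()
        assert nwk.endswith(";") and "p0" in nwk

    def test_deterministic_given_seed(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 40)),
                          index=[f"p{i}" for i in range(5)])
        a = xs.cluster_populations(df, n_boot=50, rng=np.random.default_rng(9))
        b = xs.cluster_populations(df, n_boot=50, rng=np.random.default_rng(9))
        assert a.support == b.support

    def test_random_profiles_no_universally_certain_node(self):
        """Independent profiles: across seeds, no internal clade of a random
        tree is recovered in 100% of bootstraps every time."""
        always_full = True
        for seed in range(10):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(r.normal(size=(6, 50)),
                              index=[f"p{i}" for i in range(6)])
            dend = xs.cluster_populations(df, n_boot=40, rng=r)
            if any(v < 1.0 for v in dend.support.values()):
                always_full = False
        assert not always_full

    def test_too_few_or_constant_populations_rejected(self, rng):
        with pytest.raises(ValueError, match=">=3"):
            xs.cluster_populations(pd.DataFrame(rng.normal(size=(2, 10))))
        X = rng.normal(size=(3, 10))
        X[0] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            xs.cluster_populations(pd.DataFrame(X, index=["a", "b", "c"]))


class TestSpearmanCompare:
    def test_monotone_transform_and_reversal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rho, _ = xs.spearman_compare(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho_rev, _ = xs.spearman_compare(x, -x)
        assert rho_rev == pytest.approx(-1.0)

    def test_exact_enumeration_with_tie(self):
        """n=6 with one tie: rho and p match exhaustive permutation
        enumeration over all 720 orderings."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        rho, p = xs.spearman_compare(x, y)
        import scipy.stats as st
        rx, ry = st.rankdata(x), st.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = sum(abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= obs - 1e-12
                   for perm in itertools.permutations(range(6)))
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])
        assert p == pytest.approx(hits / 720)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            xs.spearman_compare([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
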