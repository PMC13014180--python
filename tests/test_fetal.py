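import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from sulcnet.fetal import (
    coexpression_ranking,
    elbow_select,
    fit_modules,
    flatten_profiles,
    gsea_preranked,
    kmeans_sweep,
    module_prototypes,
    unflatten_profiles,
    zscore_by_timepoint,
)
from sulcnet.synthetic import ExpressionSpec, GeneSetSpec, ModuleSpec, simulate_expression

THREE_MODULES = tuple(
    ModuleSpec(n_genes=12, peak_layer=pl, peak_timepoint=pt)
    for pl, pt in ((0, 0), (2, 1), (4, 0))
)


@pytest.fixture(scope="module")
def planted():
    return simulate_expression(ExpressionSpec(n_genes=40, modules=THREE_MODULES,
                                              noise_sd=1.0, seed=11))


@pytest.fixture(scope="module")
def profiles(planted):
    return flatten_profiles(zscore_by_timepoint(planted.cube))


class TestZscoreByTimepoint:
    def test_slices_standardized(self, planted):
        z = zscore_by_timepoint(planted.cube)
        g = z.groupby(["gene", "timepoint"])["value"]
        assert np.allclose(g.mean(), 0.0, atol=1e-10)
        assert np.allclose(g.std(ddof=1), 1.0, atol=1e-10)

    def test_location_invariance(self, planted):
        cube = planted.cube.copy()
        shifted = cube.copy()
        offs = {(g, t): i * 3.0 for i, (g, t) in
                enumerate(shifted.groupby(["gene", "timepoint"]).groups)}
        shifted["value"] = shifted["value"] + [
            offs[(g, t)] for g, t in zip(shifted["gene"], shifted["timepoint"])]
        a = zscore_by_timepoint(cube)["value"].to_numpy()
        b = zscore_by_timepoint(shifted)["value"].to_numpy()
        assert np.allclose(a, b, atol=1e-10)

    def test_matches_bruteforce(self, planted):
        z = zscore_by_timepoint(planted.cube)
        cube = planted.cube
        gene = cube["gene"].iloc[0]
        tp = cube["timepoint"].iloc[0]
        mask = (cube["gene"] == gene) & (cube["timepoint"] == tp)
        raw = cube.loc[mask, "value"].to_numpy()
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.allclose(z.loc[mask, "value"].to_numpy(), expected, atol=1e-12)

    def test_constant_slice_errors(self):
        sim = simulate_expression(ExpressionSpec(n_genes=4, noise_sd=0.0, seed=0))
        with pytest.raises(ValueError, match="constant"):
            zscore_by_timepoint(sim.cube)


class TestFlattenProfiles:
    def test_toy_enumeration(self):
        rows = []
        v = 0.0
        for g in ("g1", "g2"):
            for r in ("rA", "rB"):
                for l in ("l1", "l2"):
                    for t in ("t1", "t2"):
                        rows.append({"gene": g, "region": r, "layer": l,
                                     "timepoint": t, "value": v})
                        v += 1.0
        cube = pd.DataFrame(rows)
        wide = flatten_profiles(cube, regions=["rA", "rB"], layers=["l1", "l2"],
                                timepoints=["t1", "t2"])
        assert wide.shape == (2, 8)
        # timepoint-major, then layer, then region
        assert list(wide.columns) == [
            "t1|l1|rA", "t1|l1|rB", "t1|l2|rA", "t1|l2|rB",
            "t2|l1|rA", "t2|l1|rB", "t2|l2|rA", "t2|l2|rB"]
        lookup = cube.set_index(["gene", "region", "layer", "timepoint"])["value"]
        assert wide.loc["g1", "t2|l1|rB"] == lookup[("g1", "rB", "l1", "t2")]

    def test_round_trip(self, planted):
        wide = flatten_profiles(planted.cube)
        back = unflatten_profiles(wide)
        merged = back.merge(planted.cube, on=["gene", "region", "layer", "timepoint"],
                            suffixes=("_rt", ""))
        assert np.allclose(merged["value_rt"], merged["value"], atol=1e-12)

    def test_header_decodes(self, profiles):
        for col in profiles.columns:
            t, l, r = col.split("|")
            assert t.startswith("pcw") and r.startswith("region")


class TestKmeansSweepAndElbow:
    def test_ratio_non_increasing_at_high_restarts(self, profiles):
        _, ratios = kmeans_sweep(profiles, k_min=2, k_max=8, restarts=50, seed=0)
        assert (np.diff(ratios.to_numpy()) <= 1e-9).all()

    def test_separable_clouds_tiny_ratio(self, rng):
        a = rng.normal(0, 0.1, (10, 4)) + 100
        b = rng.normal(0, 0.1, (10, 4)) - 100
        x = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(20)])
        _, ratios = kmeans_sweep(x, k_min=2, k_max=3, restarts=10, seed=0)
        assert ratios.loc[2] < 0.01

    def test_determinism(self, profiles):
        a = kmeans_sweep(profiles, k_min=2, k_max=6, restarts=10, seed=5)
        b = kmeans_sweep(profiles, k_min=2, k_max=6, restarts=10, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_series_equal(a[1], b[1])

    def test_elbow_hand_computed(self):
        ratios = pd.Series({2: 1.0, 3: 0.2, 4: 0.18, 5: 0.17})
        assert elbow_select(ratios) == 3

    def test_elbow_linear_warns_kmin(self):
        ratios = pd.Series({2: 1.0, 3: 0.8, 4: 0.6, 5: 0.4})
        with pytest.warns(UserWarning, match="curvature"):
            assert elbow_select(ratios) == 2

    def test_planted_three_modules_selected(self):
        hits = 0
        seeds = 20
        for seed in range(seeds):
            sim = simulate_expression(ExpressionSpec(
                n_genes=36, modules=THREE_MODULES, noise_sd=1.0, seed=100 + seed))
            prof = flatten_profiles(zscore_by_timepoint(sim.cube))
            res = fit_modules(prof, k_max=8, restarts=20, seed=seed)
            hits += res.k_selected == 3
        assert hits / seeds >= 0.9


class TestModulePrototypes:
    def test_identical_profiles(self):
        x = pd.DataFrame(np.tile(np.arange(6.0), (4, 1)),
                         index=[f"g{i}" for i in range(4)])
        x += np.zeros((4, 1))
        labels = pd.Series(1, index=x.index)
        degrees, protos = module_prototypes(x, labels)
        assert np.allclose(protos.loc[1], np.arange(6.0))
        assert degrees.nunique() == 1

    def test_two_gene_symmetry(self, rng):
        x = pd.DataFrame(rng.normal(size=(2, 8)), index=["a", "b"])
        labels = pd.Series(1, index=x.index)
        _, protos = module_prototypes(x, labels)
        assert np.allclose(protos.loc[1], x.mean(axis=0), atol=1e-12)

    def test_matches_weighted_mean_oracle(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 12)),
                         index=[f"g{i}" for i in range(10)])
        labels = pd.Series(1, index=x.index)
        degrees, protos = module_prototypes(x, labels)
        c = np.corrcoef(x.to_numpy())
        np.fill_diagonal(c, 0)
        d = np.clip(c, 0, None).sum(axis=1)
        expected = (d[:, None] * x.to_numpy()).sum(axis=0) / d.sum()
        assert np.allclose(protos.loc[1], expected, atol=1e-12)
        assert np.allclose(degrees.to_numpy(), d, atol=1e-12)

    def test_gene_order_invariance(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 10)),
                         index=[f"g{i}" for i in range(8)])
        labels = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=x.index)
        _, protos_a = module_prototypes(x, labels)
        perm = x.sample(frac=1.0, random_state=3)
        _, protos_b = module_prototypes(perm, labels.loc[perm.index])
        assert np.allclose(protos_a.to_numpy(), protos_b.loc[protos_a.index].to_numpy(),
                           atol=1e-12)

    def test_singleton_degree_one(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 5)), index=list("abc"))
        labels = pd.Series([1, 2, 2], index=x.index)
        degrees, _ = module_prototypes(x, labels)
        assert degrees.loc["a"] == 1.0


class TestCoexpressionRanking:
    def test_prototype_ranks_first(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 12)),
                         index=[f"g{i}" for i in range(10)])
        proto = x.iloc[0].to_numpy()
        x.loc["proto_clone"] = proto
        scores = coexpression_ranking(proto, x)
        assert scores.index[0] in ("g0", "proto_clone")
        assert scores.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_prototype_last(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 12)),
                         index=[f"g{i}" for i in range(10)])
        proto = x.iloc[0].to_numpy()
        x.loc["anti"] = -proto
        scores = coexpression_ranking(proto, x)
        assert scores.dropna().index[-1] == "anti"
        assert scores.loc["anti"] == pytest.approx(-1.0, abs=1e-12)

    def test_module_members_top_ranked(self, planted, profiles):
        res = fit_modules(profiles, k_max=8, restarts=20, seed=0)
        truth = planted.module_labels
        # pick the fitted module overlapping planted module1 most
        m1 = set(truth[truth == "module1"].index)
        best = max(set(res.labels), key=lambda m:
                   len(m1 & set(res.labels[res.labels == m].index)))
        ranking = coexpression_ranking(res.prototypes.loc[best], profiles)
        top = set(ranking.index[:len(m1)])
        assert len(top & m1) >= 0.8 * len(m1)


class TestGseaPreranked:
    def ranking(self, rng, n=50):
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    def test_single_top_gene_es_one(self, rng):
        ranked = self.ranking(rng)
        res = gsea_preranked(ranked, {"top": [ranked.index[0]]},
                             weight=1.0, n_perm=100, seed=0, min_size=1)
        assert res.table["es"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_null_p_uniform(self, rng):
        ranked = self.ranking(rng, n=80)
        sets = {f"s{i}": list(rng.choice(ranked.index, size=8, replace=False))
                for i in range(300)}
        res = gsea_preranked(ranked, sets, n_perm=200, seed=1)
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01

    def test_weight_zero_matches_ks_enumeration(self, rng):
        ranked = pd.Series(np.linspace(2, -2, 10), index=[f"g{i}" for i in range(10)])
        members = ["g1", "g4", "g7"]
        res = gsea_preranked(ranked, {"s": members}, weight=0.0, n_perm=100, seed=0)
        # brute force: running sum +1/3 on hits, -1/7 on misses
        hits = np.isin(ranked.index, members)
        running = np.cumsum(np.where(hits, 1 / 3, -1 / 7))
        expected = running[np.argmax(np.abs(running))]
        assert res.table["es"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_es_bounded(self, rng):
        ranked = self.ranking(rng, n=60)
        sets = {f"s{i}": list(rng.choice(ranked.index, size=6, replace=False))
                for i in range(20)}
        res = gsea_preranked(ranked, sets, n_perm=150, seed=2)
        assert (res.table["es"].abs() <= 1.0 + 1e-12).all()

    def test_reversal_antisymmetry_weight_zero(self, rng):
        ranked = self.ranking(rng, n=30)
        members = list(rng.choice(ranked.index, size=5, replace=False))
        a = gsea_preranked(ranked, {"s": members}, weight=0.0, n_perm=100, seed=0)
        reversed_ranked = ranked.iloc[::-1]
        b = gsea_preranked(reversed_ranked, {"s": members}, weight=0.0,
                           n_perm=100, seed=0)
        assert abs(a.table["es"].iloc[0]) == pytest.approx(
            abs(b.table["es"].iloc[0]), abs=1e-12)

    def test_min_perm_and_empty_set_errors(self, rng):
        ranked = self.ranking(rng)
        with pytest.raises(ValueError, match="n_perm"):
            gsea_preranked(ranked, {"s": [ranked.index[0]]}, n_perm=10)
        with pytest.raises(ValueError, match="empty"):
            gsea_preranked(ranked, {"s": ["absent_gene"]}, n_perm=100)


class TestEndToEnd:
    def test_pipeline_recovery_and_enrichment(self):
        spec = ExpressionSpec(
            n_genes=40, modules=THREE_MODULES, noise_sd=1.0,
            gene_sets=(GeneSetSpec("overlap_m1", 0, 0.8, size=12),
                       GeneSetSpec("random_set", 0, 0.0, size=12)),
            seed=11,
        )
        sim = simulate_expression(spec)
        prof = flatten_profiles(zscore_by_timepoint(sim.cube))
        res = fit_modules(prof, k_max=8, restarts=30, seed=1)
        # recovery is judged on module genes; background genes have no true
        # module and must land somewhere
        truth_all = sim.module_labels.reindex(res.labels.index)
        mod_genes = truth_all[truth_all != "background"].index
        ari = adjusted_rand_score(truth_all.loc[mod_genes],
                                  res.labels.loc[mod_genes])
        assert ari >= 0.9
        truth = sim.module_labels
        def best_match(name):
            members = set(truth[truth == name].index)
            return max(set(res.labels), key=lambda m:
                       len(members & set(res.labels[res.labels == m].index)))
        m1, m3 = best_match("module1"), best_match("module3")
        rank1 = coexpression_ranking(res.prototypes.loc[m1], prof)
        rank3 = coexpression_ranking(res.prototypes.loc[m3], prof)
        g1 = gsea_preranked(rank1, sim.gene_sets, n_perm=500, seed=2)
        g3 = gsea_preranked(rank3, sim.gene_sets, n_perm=500, seed=2)
        row1 = g1.table.set_index("gene_set").loc["overlap_m1"]
        row3 = g3.table.set_index("gene_set").loc["overlap_m1"]
        assert row1["es"] > 0 and row1["q"] < 0.05
        # the overlap set must not register as a positive hit for the other
        # module (z-scored module profiles compete, so genuine negative
        # enrichment is expected and allowed)
        assert row3["es"] < 0 or row3["q"] > 0.2
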