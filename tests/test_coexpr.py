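"""Coexpression network construction, clustering, eigengenes, preservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from dimorphnet import coexpr, simulate
from dimorphnet.errors import ConfigError, DataError


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = _expr([x, 2 * x + 5])
        a = coexpr.adjacency(expr, beta=6)
        assert a.iloc[0, 1] == pytest.approx(1.0)
        assert a.iloc[0, 0] == 0.0

    def test_half_correlation_power_six(self):
        # orthogonal designs give corr exactly 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0])
        y = 0.5 * x + np.sqrt(0.75) * z
        a = coexpr.adjacency(_expr([x, y]), beta=6)
        assert a.iloc[0, 1] == pytest.approx(0.5 ** 6)

    def test_invariant_to_affine_rescaling(self, rng):
        values = rng.standard_normal((10, 30))
        a1 = coexpr.adjacency(_expr(values), beta=6)
        scaled = values * rng.uniform(0.5, 3, size=(10, 1)) + \
            rng.uniform(-5, 5, size=(10, 1))
        a2 = coexpr.adjacency(_expr(scaled), beta=6)
        np.testing.assert_allclose(a1.to_numpy(), a2.to_numpy(), atol=1e-10)


class TestTopologicalOverlap:
    def _tom(self, a):
        genes = [f"g{i}" for i in range(len(a))]
        return coexpr.topological_overlap(
            pd.DataFrame(np.asarray(a, dtype=float), index=genes, columns=genes))

    def test_isolated_pair_with_full_edge(self):
        tom = self._tom([[0, 1], [1, 0]])
        assert tom.iloc[0, 1] == pytest.approx(1.0)  # (0+1)/(1+1-1)

    def test_disconnected_pair(self):
        tom = self._tom([[0, 0], [0, 0]])
        assert tom.iloc[0, 1] == pytest.approx(0.0)

    def test_triangle_half_weights(self):
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5, hand evaluation
        a = [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]
        tom = self._tom(a)
        assert tom.iloc[0, 1] == pytest.approx(0.5)

    def test_symmetry_range_unit_diagonal(self, rng):
        x = rng.uniform(0, 1, size=(15, 15))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = self._tom(a).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1.0)


class TestAgglomerative:
    def test_recovers_two_planted_blocks(self):
        cfg = simulate.SimConfig(seed=2, n_genes=30, n_samples=200,
                                 module_sizes=(10, 10), module_corr=0.9,
                                 trait_modules=(), hub_degree=10)
        expr, _, truth = simulate.simulate_expression(cfg)
        tom = coexpr.topological_overlap(coexpr.adjacency(expr, 6))
        asg = coexpr.cluster_agglomerative(tom, min_module_size=5,
                                           cut_height=0.99)
        genes = list(expr.index)
        t = [next((i for i, m in enumerate(truth.true_modules.values(), 1)
                   if g in m), 0) for g in genes]
        p = [next((i for i, m in enumerate(asg.modules.values(), 1)
                   if g in m), 0) for g in genes]
        assert len(asg.modules) == 2
        assert adjusted_rand_score(t, p) == pytest.approx(1.0)

    def test_independent_genes_yield_no_modules(self):
        clean = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            expr = _expr(rng.standard_normal((100, 200)))
            tom = coexpr.topological_overlap(coexpr.adjacency(expr, 6))
            asg = coexpr.cluster_agglomerative(tom, min_module_size=20,
                                               cut_height=0.99)
            clean += len(asg.modules) == 0
        assert clean >= 45

    def test_duplicated_gene_always_coassigned(self, rng):
        values = rng.standard_normal((20, 50))
        values[7] = values[3]  # exact duplicate -> dissTOM distance 0
        tom = coexpr.topological_overlap(coexpr.adjacency(_expr(values), 6))
        asg = coexpr.cluster_agglomerative(tom, min_module_size=2,
                                           cut_height=0.5)
        home = {g: m for m, mem in asg.modules.items() for g in mem}
        assert home.get("g3") == home.get("g7")

    def test_cut_height_validated(self, rng):
        tom = coexpr.topological_overlap(
            coexpr.adjacency(_expr(rng.standard_normal((5, 20))), 6))
        with pytest.raises(ConfigError):
            coexpr.cluster_agglomerative(tom, cut_height=1.5)


class TestDivisive:
    def _toy_two_cliques(self):
        # two 6-cliques with tight TOM, one weak bridge
        n = 12
        tom = np.full((n, n), 0.05)
        for block in (range(6), range(6, 12)):
            for i in block:
                for j in block:
                    tom[i, j] = 0.9
        tom[5, 6] = tom[6, 5] = 0.4  # bridge keeps the graph connected
        np.fill_diagonal(tom, 1.0)
        genes = [f"g{i:02d}" for i in range(n)]
        return pd.DataFrame(tom, index=genes, columns=genes)

    def test_first_split_separates_cliques(self):
        tom = self._toy_two_cliques()
        asg = coexpr.cluster_divisive_kmedoids(
            tom, k_max=2, min_module_size=3, improvement_tol=0.05,
            sparsity=1.0)
        scale1 = [m for m, s in asg.scale.items() if s == 1]
        members = {frozenset(asg.modules[m]) for m in scale1}
        expected = {frozenset(f"g{i:02d}" for i in range(6)),
                    frozenset(f"g{i:02d}" for i in range(6, 12))}
        assert members == expected

    def test_infinite_tolerance_leaves_components_whole(self):
        tom = self._toy_two_cliques()
        asg = coexpr.cluster_divisive_kmedoids(
            tom, k_max=3, min_module_size=3, improvement_tol=np.inf,
            sparsity=1.0)
        assert all(s == 0 for s in asg.scale.values())
        assert len(asg.modules) == 1  # single connected component

    def test_gene_in_one_module_per_scale(self):
        cfg = simulate.SimConfig(seed=4, n_genes=150, n_samples=150,
                                 module_sizes=(30, 40), trait_modules=())
        expr, _, _ = simulate.simulate_expression(cfg)
        tom = coexpr.topological_overlap(coexpr.adjacency(expr, 6))
        asg = coexpr.cluster_divisive_kmedoids(tom, min_module_size=10)
        by_scale: dict[int, list[set]] = {}
        for m, mem in asg.modules.items():
            by_scale.setdefault(asg.scale[m], []).append(mem)
        for scale, sets in by_scale.items():
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    assert not (sets[i] & sets[j]), f"overlap at scale {scale}"

    def test_recovers_planted_blocks_at_some_scale(self):
        hits = 0
        for seed in range(1, 21):
            cfg = simulate.SimConfig(seed=seed, n_genes=200, n_samples=200,
                                     module_sizes=(30, 40, 50),
                                     trait_modules=())
            expr, _, truth = simulate.simulate_expression(cfg)
            tom = coexpr.topological_overlap(coexpr.adjacency(expr, 6))
            asg = coexpr.cluster_divisive_kmedoids(tom, min_module_size=10)
            rec = sum(
                max((len(m & t) / len(m | t) for m in asg.modules.values()),
                    default=0.0) >= 0.8
                for t in truth.true_modules.values())
            hits += rec >= 2
        assert hits >= 15


class TestEigengene:
    def test_identical_genes_rank_one(self, rng):
        profile = rng.standard_normal(40)
        expr = _expr([profile, profile * 2 + 1, profile * -0 + profile])
        eig = coexpr.module_eigengene(expr, set(expr.index))
        assert eig.variance_explained == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig.values, z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign convention: positive average gene correlation

    def test_independent_genes_variance_explained(self, rng):
        size, n = 10, 2000
        expr = _expr(rng.standard_normal((size, n)))
        eig = coexpr.module_eigengene(expr, set(expr.index))
        assert 0.5 / size <= eig.variance_explained <= 1.5 / size

    def test_sign_flip_invariance(self, rng):
        values = rng.standard_normal((8, 30))
        e1 = coexpr.module_eigengene(_expr(values), {f"g{i}" for i in range(8)})
        e2 = coexpr.module_eigengene(_expr(-values), {f"g{i}" for i in range(8)})
        np.testing.assert_allclose(e1.values.to_numpy(), -e2.values.to_numpy(),
                                   atol=1e-10)

    def test_too_small_module_rejected(self, rng):
        expr = _expr(rng.standard_normal((5, 20)))
        with pytest.raises(DataError):
            coexpr.module_eigengene(expr, {"g0"})


class TestTraitCorrelation:
    def test_eigengene_equal_to_trait(self, rng):
        vals = pd.Series(rng.standard_normal(50),
                         index=[f"s{j}" for j in range(50)])
        eig = coexpr.Eigengene("m", vals, 1.0)
        tc = coexpr.module_trait_correlation(eig, vals)
        assert tc.r == pytest.approx(1.0)
        assert tc.passes

    def test_p_matches_t_distribution_oracle(self):
        # r = 0.5 at n = 200: t = r sqrt((n-2)/(1-r^2)) = 8.124, df = 198
        n = 200
        x = np.zeros(n)
        x[::2] = 1.0
        z = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        y = 0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * (z - z.mean()) / z.std()
        samples = [f"s{j}" for j in range(n)]
        eig = coexpr.Eigengene("m", pd.Series(x, index=samples), 1.0)
        tc = coexpr.module_trait_correlation(eig, pd.Series(y, index=samples))
        assert tc.r == pytest.approx(0.5, abs=1e-12)
        expected = 2 * stats.t.sf(0.5 * np.sqrt(198 / 0.75), 198)
        assert tc.p == pytest.approx(expected, rel=1e-9)
        assert tc.p == pytest.approx(4.774e-14, rel=1e-3)
        assert tc.passes

    def test_null_pass_rate_matches_threshold(self, rng):
        # 10,000 independent pairs: pass rate should sit at the nominal 1e-3
        n, trials = 200, 10_000
        x = rng.standard_normal((trials, n))
        y = rng.standard_normal((trials, n))
        x = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        y = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
        r = (x * y).mean(axis=1)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        assert (p < 1e-3).mean() <= 2e-3

    def test_constant_trait_rejected(self, rng):
        vals = pd.Series(rng.standard_normal(20),
                         index=[f"s{j}" for j in range(20)])
        eig = coexpr.Eigengene("m", vals, 1.0)
        with pytest.raises(DataError):
            coexpr.module_trait_correlation(
                eig, pd.Series(1.0, index=vals.index))


class TestCalibrateFpr:
    def test_threshold_one_passes_everything(self, rng):
        expr = _expr(rng.standard_normal((60, 50)))
        trait = pd.Series(rng.standard_normal(50), index=expr.columns)
        fpr, table = coexpr.calibrate_fpr(expr, trait, n_sets=100,
                                          size_range=(5, 20), p_threshold=1.0,
                                          seed=0)
        assert fpr == 1.0
        assert table["passes"].all()

    def test_independent_data_matches_nominal_alpha(self, rng):
        # independent expression and trait: FPR tracks the nominal 1e-3,
        # far below the 0.1 seen on correlated real-data eigengenes
        total_fp = total = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            expr = _expr(r.standard_normal((300, 100)))
            trait = pd.Series(r.standard_normal(100), index=expr.columns)
            fpr, table = coexpr.calibrate_fpr(expr, trait, n_sets=400,
                                              size_range=(20, 300), seed=seed)
            total_fp += int(table["passes"].sum())
            total += len(table)
            assert 0 <= fpr <= 0.01
        assert total_fp / total <= 0.01


class TestPreservation:
    def test_planted_module_preserved_in_identical_data(self):
        cfg = simulate.SimConfig(seed=6, n_genes=200, module_sizes=(30,),
                                 module_corr=0.64, trait_modules=())
        expr, _, truth = simulate.simulate_expression(cfg)
        res = coexpr.module_preservation(truth.true_modules, expr, expr,
                                         n_perm=100, seed=1)
        assert len(res) == 1 and res[0].preserved

    def test_random_size_matched_module_not_preserved(self):
        flagged = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr = _expr(r.standard_normal((150, 100)))
            module = {"random": set(r.choice(expr.index, 30, replace=False))}
            res = coexpr.module_preservation(module, expr, expr,
                                             n_perm=100, seed=seed)
            flagged += res[0].preserved
        assert flagged <= 1

    def test_small_shared_overlap_skipped(self, rng):
        expr = _expr(rng.standard_normal((30, 40)))
        res = coexpr.module_preservation(
            {"tiny": {"g0", "g1", "g2"}}, expr, expr, n_perm=50, seed=0)
        assert res == []
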