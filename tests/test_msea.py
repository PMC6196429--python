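"""Marker mapping, LD pruning, the quantile chi statistic, and its null."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from dimorphnet import msea, simulate
from dimorphnet.errors import DataError


def _eqtl(rows):
    return pd.DataFrame(rows, columns=["snp", "gene", "pvalue", "snp_pos",
                                       "gene_start", "gene_end"])


class TestMapGenes:
    def test_window_and_pvalue_boundaries(self):
        start, end = 5_000_000, 5_010_000
        eqtl = _eqtl([
            ("rs_in", "g1", 1e-8, start - 500_000, start, end),
            ("rs_out", "g1", 1e-8, start - 1_000_001, start, end),
            ("rs_weak", "g1", 1e-5, start, start, end),
        ])
        snps = msea.map_genes_to_esnps({"g1"}, eqtl)
        assert snps == {"rs_in"}

    def test_exact_window_edge_included(self):
        start, end = 5_000_000, 5_010_000
        eqtl = _eqtl([("rs_edge", "g1", 1e-8, start - 1_000_000, start, end)])
        assert msea.map_genes_to_esnps({"g1"}, eqtl) == {"rs_edge"}

    def test_absent_gene_contributes_nothing(self):
        eqtl = _eqtl([("rs1", "g1", 1e-8, 100, 100, 200)])
        assert msea.map_genes_to_esnps({"g_missing"}, eqtl) == set()


class TestPruneLd:
    def _gwas(self, snps):
        return pd.DataFrame({"snp": snps, "chrom": "c",
                             "pos": range(len(snps)),
                             "pvalue": np.linspace(0.1, 0.9, len(snps))})

    def test_one_per_block(self):
        snps = [f"rs{i}" for i in range(5)]
        eqtl = _eqtl([(s, "g1", 1e-8 * (i + 1), 1, 1, 2)
                      for i, s in enumerate(snps)])
        kept = msea.prune_ld(snps, {s: "b1" for s in snps}, eqtl,
                             self._gwas(snps))
        assert kept == {"rs0"}  # best eQTL P

    def test_distinct_blocks_identity(self):
        snps = [f"rs{i}" for i in range(4)]
        eqtl = _eqtl([(s, "g1", 1e-8, 1, 1, 2) for s in snps])
        kept = msea.prune_ld(snps, {s: f"b{i}" for i, s in enumerate(snps)},
                             eqtl, self._gwas(snps))
        assert kept == set(snps)

    def test_two_blocks_exactly_one_each(self):
        # brute-force: every valid selection keeps one per block
        snps = [f"rs{i}" for i in range(5)]
        ld = {"rs0": "b1", "rs1": "b1", "rs2": "b1", "rs3": "b2", "rs4": "b2"}
        eqtl = _eqtl([(s, "g1", 1e-7, 1, 1, 2) for s in snps])
        kept = msea.prune_ld(snps, ld, eqtl, self._gwas(snps))
        valid = [set(pair) for pair in
                 product(["rs0", "rs1", "rs2"], ["rs3", "rs4"])]
        assert kept in valid
        assert len(kept) == 2

    def test_unknown_snp_gets_singleton_block(self):
        snps = ["rs0", "rs1"]
        eqtl = _eqtl([(s, "g1", 1e-8, 1, 1, 2) for s in snps])
        kept = msea.prune_ld(snps, {}, eqtl, self._gwas(snps))
        assert kept == set(snps)


class TestChiStatistic:
    def test_set_equal_to_background_gives_zero(self, rng):
        bg = rng.uniform(0, 1, 2000)
        comp = msea.chi_statistic(bg, bg)
        np.testing.assert_allclose(comp.observed, comp.expected)
        assert comp.chi == pytest.approx(0.0)

    def test_single_quantile_hand_value(self):
        # one point at the median: O=2, E=1 -> chi = (2-1)/(1+1) = 0.5
        bg = np.linspace(0.1, 1.0, 10)
        comp = msea.chi_statistic([0.1, 0.2], bg, n_quantiles=1,
                                  top_range=(0.5, 0.5))
        assert comp.observed[0] == 2
        assert comp.expected[0] == pytest.approx(1.0)
        assert comp.chi == pytest.approx(0.5)

    def test_counts_monotone_in_stringency(self, rng):
        bg = rng.uniform(0, 1, 5000)
        comp = msea.chi_statistic(rng.choice(bg, 100, replace=False), bg)
        # ascending f = more stringent cutoffs = smaller counts
        assert (np.diff(comp.observed) <= 0).all()
        assert (np.diff(comp.expected) <= 0).all()

    def test_invariant_under_monotone_transform(self, rng):
        for _ in range(100):
            bg = rng.uniform(0, 1, 500)
            idx = rng.choice(500, size=40, replace=False)
            chi1 = msea.chi_statistic(bg[idx], bg).chi
            chi2 = msea.chi_statistic(bg[idx] ** 2, bg ** 2).chi
            assert chi1 == pytest.approx(chi2, abs=1e-10)

    def test_background_markers_perturb_chi_by_mean_zero_noise(self, rng):
        bg = rng.uniform(0, 1, 5000)
        base_idx = rng.choice(5000, size=60, replace=False)
        base = bg[base_idx]
        base_chi = msea.chi_statistic(base, bg).chi
        deltas = []
        for _ in range(100):
            extra = rng.choice(bg, size=40, replace=True)
            deltas.append(msea.chi_statistic(
                np.concatenate([base, extra]), bg).chi - base_chi)
        deltas = np.asarray(deltas)
        assert abs(deltas.mean()) <= 3 * deltas.std(ddof=1) / 10 + 1e-9

    def test_empty_set_rejected(self, rng):
        with pytest.raises(DataError):
            msea.chi_statistic([], rng.uniform(0, 1, 100))


class TestBh:
    def test_hand_example(self):
        # min(0.01*2/1, adj(0.04*2/2)) = 0.02, 0.04
        np.testing.assert_allclose(msea.bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(msea.bh_fdr([0.03]), [0.03])


@pytest.fixture(scope="module")
def null_world():
    cfg = simulate.SimConfig(seed=17, n_genes=300, n_snps=6000,
                             module_sizes=(20, 30), enriched_pathways=())
    pathways = simulate.simulate_pathways(cfg)
    gwas, eqtl, ld = simulate.simulate_genetics(cfg, pathways)
    index = msea.MseaIndex(gwas, eqtl, ld)
    return index, sorted(index.mapped_genes)


class TestMseaPvalue:
    def test_observed_at_null_mean_gives_half(self, null_world):
        index, universe = null_world
        null = index.null_chis(40, universe, n_null=500, seed=1)
        p, _, mean, _ = msea.msea_pvalue(float(null.mean()), 40, index,
                                         universe, n_null=500, seed=1)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_empirical_p_never_zero(self, null_world):
        index, universe = null_world
        _, emp, _, _ = msea.msea_pvalue(1e9, 40, index, universe,
                                        n_null=500, seed=1)
        assert emp == pytest.approx(1 / 501, rel=1e-6)

    def test_small_n_null_rejected(self, null_world):
        index, universe = null_world
        with pytest.raises(DataError):
            msea.msea_pvalue(0.0, 40, index, universe, n_null=50)


class TestRunMsea:
    def test_single_set_fdr_equals_pvalue(self, small_cohort):
        _, data = small_cohort
        table = msea.run_msea({"only": data["pathways"]["pathway_2"]},
                              data["gwas"], data["eqtl"], data["ld"],
                              n_null=200, seed=0)
        row = table.iloc[0]
        assert row["fdr"] == pytest.approx(row["pvalue"])

    def test_planted_set_detected(self, small_cohort):
        _, data = small_cohort
        table = msea.run_msea(data["pathways"], data["gwas"], data["eqtl"],
                              data["ld"], n_null=500, seed=0)
        planted = set(data["truth"].true_enriched_sets)
        sig = set(table[table["significant"]]["set_id"])
        assert planted <= sig

    def test_unmapped_set_excluded_from_fdr(self, small_cohort):
        _, data = small_cohort
        sets = {"mapped": data["pathways"]["pathway_2"],
                "ghost": {"NOT_A_GENE_1", "NOT_A_GENE_2"}}
        table = msea.run_msea(sets, data["gwas"], data["eqtl"], data["ld"],
                              n_null=200, seed=0)
        ghost = table[table["set_id"] == "ghost"].iloc[0]
        assert ghost["status"] == "unmapped"
        assert np.isnan(ghost["fdr"]) and not ghost["significant"]

    def test_empty_collection_rejected(self, small_cohort):
        _, data = small_cohort
        with pytest.raises(DataError):
            msea.run_msea({}, data["gwas"], data["eqtl"], data["ld"])

    def test_deterministic_given_seed(self, small_cohort):
        _, data = small_cohort
        kwargs = dict(n_null=200, seed=5)
        t1 = msea.run_msea(data["pathways"], data["gwas"], data["eqtl"],
                           data["ld"], **kwargs)
        t2 = msea.run_msea(data["pathways"], data["gwas"], data["eqtl"],
                           data["ld"], **kwargs)
        pd.testing.assert_frame_equal(t1, t2)


class TestPowerMonotonicity:
    def test_planted_chi_grows_as_enrichment_strengthens(self):
        # smaller Beta shape = stronger enrichment = larger chi, on average
        strengths = [1.0, 0.6, 0.2]
        mean_chi = []
        for a in strengths:
            chis = []
            for seed in range(1, 11):
                cfg = simulate.SimConfig(
                    seed=seed, n_genes=400, n_snps=6000,
                    module_sizes=(20, 30), n_pathways=5,
                    enriched_pathways=(0,), gwas_enrich_strength=a)
                pathways = simulate.simulate_pathways(cfg)
                gwas, eqtl, ld = simulate.simulate_genetics(cfg, pathways)
                index = msea.MseaIndex(gwas, eqtl, ld)
                chis.append(index.chi(pathways["pathway_1"])[0])
            mean_chi.append(np.mean(chis))
        assert mean_chi[0] < mean_chi[1] < mean_chi[2]
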