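"""Genotype filtering, fdSV scan, pathway test, kinship, MLM GWAS and
diversity statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pansv import popgen
from pansv.popgen import SVGenotypeMatrix
from pansv.sim import SimConfig, simulate_population


def matrix_from(geno, positions=None):
    geno = pd.DataFrame(
        geno, index=[f"sv{i}" for i in range(len(geno))],
        columns=[f"ind{j}" for j in range(len(geno[0]))], dtype=float)
    if positions is None:
        positions = range(0, 1000 * len(geno), 1000)
    pos = pd.DataFrame({"chrom": "chr1", "pos": list(positions)},
                       index=geno.index)
    return SVGenotypeMatrix(genotypes=geno, positions=pos)


class TestFilterGenotypes:
    def test_maf_boundaries(self):
        # 10 individuals: MAF = mean/2
        low = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]       # f = 0.05 -> kept
        lower = [0.0] * 10
        lower[0] = 0.8                              # not integral; use dosage
        gm = matrix_from([low, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]])
        out, removed = popgen.filter_genotypes(gm)
        assert list(out.genotypes.index) == ["sv0", "sv1"]

        gm2 = matrix_from([[0, 0, 0, 0, 0, 0, 0, 0, 0, 1],
                           [0, 0, 0, 0, 0, 0, 0, 0, 0, 0]])
        # sv0 f = 0.05 kept; sv1 monomorphic removed
        out2, removed2 = popgen.filter_genotypes(gm2)
        assert list(out2.genotypes.index) == ["sv0"]
        assert removed2["monomorphic"] == 1

    def test_maf_below_threshold_removed(self):
        row = [0.0] * 25
        row[0] = 2.0  # f = 0.04
        gm = matrix_from([row, [1] * 25])
        out, removed = popgen.filter_genotypes(gm)
        assert "sv0" not in out.genotypes.index
        assert removed["low_maf"] == 1

    def test_missing_rate_boundary(self):
        ok = [1, 0, 1, 0, 1, 0, 1, 0, np.nan, np.nan]       # miss 0.2 > 0.1
        gm = matrix_from([ok])
        out, removed = popgen.filter_genotypes(gm)
        assert len(out.genotypes) == 0 and removed["high_missing"] == 1
        boundary = [1, 0, 1, 0, 1, 0, 1, 0, 1, np.nan]      # miss exactly 0.1
        out2, _ = popgen.filter_genotypes(matrix_from([boundary]))
        assert len(out2.genotypes) == 1


class TestFdsvScan:
    def test_delta_f_arithmetic(self):
        # 4 + 4 individuals; sv0: f 0.875 vs 0.125
        geno = [[2, 2, 2, 1, 0, 0, 0, 1],
                [1, 1, 1, 1, 1, 1, 1, 1]]
        gm = matrix_from(geno)
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=gm.genotypes.columns)
        scan = popgen.fdsv_scan(gm, groups, window=10_000, step=10_000)
        assert scan.fdsv.loc["sv0", "delta_f"] == pytest.approx(0.75)
        assert bool(scan.fdsv.loc["sv0", "is_fdsv"])
        assert scan.fdsv.loc["sv1", "delta_f"] == 0

    def test_label_symmetry(self):
        gm, phen, _ = simulate_population(SimConfig(seed=5))
        groups = phen["climate_group"]
        flipped = groups.map({"tropical": "temperate",
                              "temperate": "tropical"})
        s1 = popgen.fdsv_scan(gm, groups)
        s2 = popgen.fdsv_scan(gm, flipped)
        pd.testing.assert_series_equal(s1.fdsv["delta_f"], s2.fdsv["delta_f"])
        pd.testing.assert_frame_equal(
            s1.windows[["chrom", "start", "statistic", "is_sweep"]],
            s2.windows[["chrom", "start", "statistic", "is_sweep"]])

    def test_no_groups_differ_no_fdsv(self):
        gm, phen, _ = simulate_population(
            SimConfig(seed=6), group_delta_f=0.0, fst=0.0)
        scan = popgen.fdsv_scan(gm, phen["climate_group"])
        assert scan.fdsv["is_fdsv"].sum() == 0

    def test_implanted_cluster_lands_in_top_percent(self):
        gm, phen, truth = simulate_population(
            SimConfig(seed=2), n_svs=10_000)
        scan = popgen.fdsv_scan(gm, phen["climate_group"])
        chrom, lo, hi = truth.cluster_region
        assert any(c == chrom and s < hi and lo < e
                   for c, s, e in scan.sweep_regions)

    def test_empty_windows_excluded(self):
        gm = matrix_from([[1, 0, 1, 0]], positions=[500_000])
        groups = pd.Series(["a", "a", "b", "b"],
                           index=gm.genotypes.columns)
        scan = popgen.fdsv_scan(gm, groups)
        assert (scan.windows["n_svs"] >= 1).all()


class TestPathwayEnrichment:
    def test_hand_computed_chi_squared(self):
        """Statistic and p match the manual sum((O-E)^2/E) for the 2x2 table
        [[20, 80], [50, 850]]."""
        universe = {f"g{i}" for i in range(1000)}
        sweep = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(20)} | \
            {f"g{i}" for i in range(100, 150)}
        res = popgen.pathway_enrichment(sweep, {"er": pathway}, universe)
        table = np.array([[20, 80], [50, 850]])
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / table.sum()
        chi2_manual = ((table - expected) ** 2 / expected).sum()
        assert res.loc["er", "chi2"] == pytest.approx(chi2_manual)
        assert res.loc["er", "p"] == pytest.approx(
            stats.chi2.sf(chi2_manual, 1))

    def test_identical_proportions_p_near_one(self):
        universe = {f"g{i}" for i in range(200)}
        sweep = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(0, 200, 2)}  # half of each stratum
        res = popgen.pathway_enrichment(sweep, {"p": pathway}, universe)
        assert res.loc["p", "chi2"] == pytest.approx(0.0, abs=1e-9)

    def test_small_cells_switch_to_fisher(self):
        universe = {f"g{i}" for i in range(1000)}
        sweep = {"g0", "g1"}
        pathway = {"g0", "g2"}
        res = popgen.pathway_enrichment(sweep, {"tiny": pathway}, universe)
        assert res.loc["tiny", "method"] == "fisher"

    def test_empty_pathway_raises(self):
        with pytest.raises(ValueError, match="no genes"):
            popgen.pathway_enrichment({"g0"}, {"empty": {"zz"}},
                                      {"g0", "g1"})


class TestKinshipAndPcs:
    def test_diagonal_and_duplicates(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(100, 10)).astype(float)
        geno[:, 1] = geno[:, 0]  # duplicated individual
        gm = matrix_from(geno.tolist())
        K, S, excluded = popgen.build_kinship_and_pcs(gm)
        assert np.allclose(np.diag(K), 1.0)
        assert K.iloc[0, 1] == pytest.approx(1.0)
        assert excluded == []

    def test_high_missing_individual_excluded(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(50, 6)).astype(float)
        geno[:40, 2] = np.nan
        gm = matrix_from(geno.tolist())
        K, S, excluded = popgen.build_kinship_and_pcs(gm)
        assert excluded == ["ind2"]
        assert "ind2" not in K.index

    def test_pc1_separates_two_clusters(self):
        from sklearn.metrics import silhouette_score

        gm, phen, _ = simulate_population(SimConfig(seed=4), fst=0.3)
        K, S, _ = popgen.build_kinship_and_pcs(gm)
        labels = phen.loc[S.index, "climate_group"]
        score = silhouette_score(S[["PC1"]], labels)
        assert score > 0.5


class TestPavGwasMlm:
    def test_identity_kinship_collapses_to_ols(self):
        """With K = I the mixed model equals per-marker OLS regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n, m = 80, 30
        geno = rng.binomial(2, 0.4, size=(m, n)).astype(float)
        gm = matrix_from(geno.tolist())
        y = pd.Series(rng.normal(size=n), index=gm.genotypes.columns)
        K = pd.DataFrame(np.eye(n), index=gm.genotypes.columns,
                         columns=gm.genotypes.columns)
        S = pd.DataFrame(rng.normal(size=(n, 3)),
                         index=gm.genotypes.columns,
                         columns=["PC1", "PC2", "PC3"])
        res = popgen.pav_gwas_mlm(y, gm, K, S)
        for sv in ["sv0", "sv7", "sv29"]:
            X = sm.add_constant(np.column_stack(
                [S.to_numpy(), gm.genotypes.loc[sv].to_numpy()]))
            ols = sm.OLS(y.to_numpy(), X).fit()
            assert res.loc[sv, "p"] == pytest.approx(ols.pvalues[-1], rel=1e-6)
            assert res.loc[sv, "beta"] == pytest.approx(ols.params[-1],
                                                        rel=1e-6)

    def test_per_marker_reml_agrees_with_ppd(self):
        gm, phen, truth = simulate_population(SimConfig(seed=1), n_svs=60)
        fgm, _ = popgen.filter_genotypes(gm)
        K, S, _ = popgen.build_kinship_and_pcs(fgm)
        fast = popgen.pav_gwas_mlm(phen["trait"], fgm, K, S)
        slow = popgen.pav_gwas_mlm(phen["trait"], fgm, K, S,
                                   reml_per_marker=True)
        logf = -np.log10(fast["p"].astype(float))
        logs = -np.log10(slow["p"].astype(float))
        assert np.corrcoef(logf, logs)[0, 1] > 0.98

    def test_causal_sv_detected(self):
        gm, phen, truth = simulate_population(SimConfig(seed=7))
        fgm, _ = popgen.filter_genotypes(gm)
        K, S, _ = popgen.build_kinship_and_pcs(fgm)
        res = popgen.pav_gwas_mlm(phen["trait"], fgm, K, S)
        assert res.loc[truth.causal_sv, "logp"] > 5
        assert bool(res.loc[truth.causal_sv, "significant"])

    def test_null_calibration_and_inflation(self):
        """Pure polygenic null: type-I error near 0.05 and lambda_GC in
        [0.9, 1.1]."""
        gm, phen, _ = simulate_population(SimConfig(seed=11), causal_h2=0.0)
        fgm, _ = popgen.filter_genotypes(gm)
        K, S, _ = popgen.build_kinship_and_pcs(fgm)
        res = popgen.pav_gwas_mlm(phen["trait"], fgm, K, S)
        pvals = res["p"].dropna()
        assert 0.03 <= (pvals < 0.05).mean() <= 0.07
        assert 0.9 <= popgen.genomic_inflation(pvals) <= 1.1

    def test_too_few_individuals(self):
        gm = matrix_from([[0, 1, 2, 1]])
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=gm.genotypes.columns)
        K = pd.DataFrame(np.eye(4), index=gm.genotypes.columns,
                         columns=gm.genotypes.columns)
        S = pd.DataFrame(np.zeros((4, 3)), index=gm.genotypes.columns)
        with pytest.raises(ValueError):
            popgen.pav_gwas_mlm(y, gm, K, S)


class TestDiversityStats:
    def test_two_haplotypes_single_difference(self):
        hap = np.zeros((1000, 2))
        hap[0, 1] = 1
        df = popgen.pi_windows(pd.DataFrame(hap),
                               pd.Series(range(1000)), window=1000)
        assert df["pi"].iloc[0] == pytest.approx(1 / 1000)

    def test_monomorphic_window(self):
        hap = np.zeros((100, 4))
        df = popgen.pi_windows(pd.DataFrame(hap),
                               pd.Series(range(100)), window=100)
        assert df["pi"].iloc[0] == 0
        assert popgen.shannon_index(pd.DataFrame(hap)) == 0

    def test_pi_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        n_sites, n_hap = 200, 4
        hap = rng.integers(0, 2, size=(n_sites, n_hap)).astype(float)
        df = popgen.pi_windows(pd.DataFrame(hap),
                               pd.Series(range(n_sites)), window=n_sites)
        diffs = [np.mean(hap[:, i] != hap[:, j])
                 for i, j in itertools.combinations(range(n_hap), 2)]
        assert df["pi"].iloc[0] == pytest.approx(np.mean(diffs))

    def test_pi_bounded_by_half(self):
        rng = np.random.default_rng(2)
        hap = rng.integers(0, 2, size=(500, 20)).astype(float)
        df = popgen.pi_windows(pd.DataFrame(hap),
                               pd.Series(range(500)), window=100)
        assert (df["pi"] >= 0).all()
        # n/(n-1)-corrected heterozygosity can reach at most ~0.526 at n=20
        assert (df["pi"] <= 0.5 * 20 / 19 + 1e-12).all()

    def test_shannon_positive_and_additive(self):
        rng = np.random.default_rng(3)
        hap = rng.integers(0, 2, size=(50, 10)).astype(float)
        h_all = popgen.shannon_index(pd.DataFrame(hap))
        h_half1 = popgen.shannon_index(pd.DataFrame(hap[:25]))
        h_half2 = popgen.shannon_index(pd.DataFrame(hap[25:]))
        assert h_all == pytest.approx(h_half1 + h_half2)
        assert h_all > 0

    def test_density_correlation_identical_cohorts(self):
        rng = np.random.default_rng(4)
        pos = rng.integers(0, 1_000_000, size=2000)
        rho, p = popgen.windowed_density_correlation(pos, pos, 50_000)
        assert rho == pytest.approx(1.0)
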