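"""DEG calling, enrichment, correlation screen and the HR fixed-SV pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pansv import expression as ex
from pansv.core import GeneModel
from pansv.sim import (
    ExpressionDesign, SimConfig, implant_svs, make_reference,
    simulate_expression,
)

from conftest import expression_from_arrays, make_sv


class TestBhAdjust:
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_definition(self, pvals):
        """BH output equals the brute-force step-up definition."""
        adj = ex.bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            brute[i] = running
        assert np.allclose(adj, brute)


class TestCallDegs:
    def test_identical_groups_not_deg(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(50, 6))
        counts = np.hstack([counts, counts])  # group2 literally identical
        mat = expression_from_arrays(counts)
        degs = ex.call_degs(mat, [f"s{i}" for i in range(6)],
                            [f"s{i}" for i in range(6, 12)])
        assert np.allclose(degs["log2fc"], 0)
        assert not degs["is_deg"].any()

    def test_fold_change_threshold_is_binding(self):
        """A clear but sub-2-fold shift stays below the DEG rule regardless
        of its p-value."""
        rng = np.random.default_rng(1)
        stable = rng.poisson(1000, size=(50, 80)).astype(float)
        base = rng.poisson(1000, size=(1, 40)).astype(float)
        gene = np.hstack([base * 1.6, base])  # |log2fc| ~ 0.68 < 1
        counts = np.vstack([gene, stable])
        mat = expression_from_arrays(counts)
        degs = ex.call_degs(mat, [f"s{i}" for i in range(40)],
                            [f"s{i}" for i in range(40, 80)])
        assert degs.loc["g0", "padj"] < 0.05
        assert 0.3 < abs(degs.loc["g0", "log2fc"]) < 1
        assert not degs.loc["g0", "is_deg"]

    def test_requires_two_replicates(self):
        mat = expression_from_arrays(np.ones((5, 3)))
        with pytest.raises(ValueError):
            ex.call_degs(mat, ["s0"], ["s1", "s2"])

    def test_all_zero_genes_excluded(self):
        counts = np.vstack([np.zeros((1, 6)), np.ones((4, 6)) * 50])
        mat = expression_from_arrays(counts)
        degs = ex.call_degs(mat, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert "g0" not in degs.index and len(degs) == 4

    def test_power_matches_monte_carlo_oracle(self):
        """Detection power for a 4-fold change (NB dispersion 0.1, 3 vs 3,
        500 genes) agrees between two independent simulation arms within
        5 points."""
        def one_arm(seed):
            rng = np.random.default_rng(seed)
            G, phi = 500, 0.1
            mu = np.full(G, 200.0)
            mu1 = np.where(np.arange(G) < G // 2, mu * 4, mu)  # half shifted
            lam1 = rng.gamma(1 / phi, mu1[:, None] * phi, size=(G, 3))
            lam2 = rng.gamma(1 / phi, mu[:, None] * phi, size=(G, 3))
            counts = np.hstack([rng.poisson(lam1), rng.poisson(lam2)])
            mat = expression_from_arrays(counts)
            degs = ex.call_degs(mat, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
            shifted = [f"g{i}" for i in range(G // 2)]
            return degs.loc[degs.index.intersection(shifted), "is_deg"].mean()

        assert one_arm(10) == pytest.approx(one_arm(20), abs=0.05)


class TestDegProportionBySv:
    def make_degs(self, flags):
        return pd.DataFrame({"is_deg": flags},
                            index=[f"g{i}" for i in range(len(flags))])

    def test_constructed_shares(self):
        degs = self.make_degs([True] * 10 + [False] * 10
                              + [True] * 5 + [False] * 15)
        sv = {f"g{i}" for i in range(20)}
        nsv = {f"g{i}" for i in range(20, 40)}
        res = ex.deg_proportion_by_sv(degs, sv, nsv)
        assert res["sv_share"] == 0.5 and res["nsv_share"] == 0.25
        assert res["difference"] == pytest.approx(0.25)

    def test_no_degs_both_zero(self):
        degs = self.make_degs([False] * 10)
        res = ex.deg_proportion_by_sv(degs, {"g0", "g1"}, {"g2", "g3"})
        assert res["sv_share"] == 0 and res["nsv_share"] == 0

    def test_empty_set_undefined(self):
        degs = self.make_degs([True] * 4)
        res = ex.deg_proportion_by_sv(degs, set(), {"g0"})
        assert res["sv_share"] is None

    def test_overlapping_sets_rejected(self):
        degs = self.make_degs([True] * 4)
        with pytest.raises(ValueError):
            ex.deg_proportion_by_sv(degs, {"g0"}, {"g0", "g1"})


class TestSvProximityEnrichment:
    def assignments(self):
        return pd.DataFrame({
            "sv_id": [f"sv{i}" for i in range(20)],
            "accession": "accA",
            "category": ["DELup"] * 10 + ["INSdown"] * 10,
            "gene_id": [f"g{i}" for i in range(20)],
        })

    def test_altered_everything_fold_one(self):
        universe = {f"g{i}" for i in range(40)}
        res = ex.sv_proximity_enrichment(
            self.assignments(), {"accA": universe}, universe,
            n_shuffles=100, seed=0)
        assert np.allclose(res["fold"], 1.0)
        assert (res["p"] > 0.5).all()

    def test_category_fully_altered_fold_two(self):
        universe = {f"g{i}" for i in range(40)}
        altered = {f"g{i}" for i in range(10)} | \
            {f"g{i}" for i in range(20, 30)}  # DELup genes + half the rest
        res = ex.sv_proximity_enrichment(
            self.assignments(), {"accA": altered}, universe,
            n_shuffles=400, seed=0)
        delup = res[res["category"] == "DELup"].iloc[0]
        assert delup["fold"] == pytest.approx(2.0, rel=0.1)
        assert delup["p"] < 0.05

    def test_implanted_cis_effects_reach_significance(self):
        """Genes with implanted cis-SV effects are expression-altered, so
        the SV categories tagging them enrich at q < 0.05."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        cat_genes = genes[:30]
        altered = set(cat_genes) | set(
            np.array(genes[30:])[rng.random(170) < 0.1])
        df = pd.DataFrame({"sv_id": [f"sv{i}" for i in range(30)],
                           "accession": "accA", "category": "DELup",
                           "gene_id": cat_genes})
        res = ex.sv_proximity_enrichment(df, {"accA": altered}, set(genes),
                                         n_shuffles=999, seed=1)
        assert (res["q"] < 0.05).all()


class TestCorrelateTfTargets:
    def test_exact_copy_passes(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=16)
        tf = pd.DataFrame([v], index=["tf1"])
        tg = pd.DataFrame([v, rng.normal(size=16)], index=["t1", "t2"])
        res = ex.correlate_tf_targets(tf, tg)
        row = res["pairs"].set_index(["tf", "target"]).loc[("tf1", "t1")]
        assert row["rho"] == pytest.approx(1.0)
        assert row["passes"]

    def test_share_rounding(self):
        assert ex.pass_share(325, 540) == 60.2
        assert ex.pass_share(16, 32) == 50.0

    def test_constant_vector_excluded(self):
        tf = pd.DataFrame([np.ones(8)], index=["flat"])
        tg = pd.DataFrame([np.arange(8.0)], index=["t1"])
        res = ex.correlate_tf_targets(tf, tg)
        assert res["pairs"].empty

    def test_too_few_samples(self):
        tf = pd.DataFrame([[1.0, 2.0, 3.0]], index=["tf1"])
        with pytest.raises(ValueError):
            ex.correlate_tf_targets(tf, tf)

    def test_null_pass_rate_matches_simulation_oracle(self):
        """Independent Gaussian pairs at n=16: the screen's pass rate agrees
        with a direct Monte-Carlo estimate of P(rho >= 0.6 and p < 0.05)."""
        rng = np.random.default_rng(2)
        n_pairs = 600
        hits = 0
        for _ in range(n_pairs):
            r, p = stats.pearsonr(rng.normal(size=16), rng.normal(size=16))
            hits += (r >= 0.6 and p < 0.05)
        oracle_rate = hits / n_pairs

        tf = pd.DataFrame(rng.normal(size=(1, 16)), index=["tf1"])
        tg = pd.DataFrame(rng.normal(size=(n_pairs, 16)),
                          index=[f"t{i}" for i in range(n_pairs)])
        res = ex.correlate_tf_targets(tf, tg)
        rate = res["pairs"]["passes"].mean()
        assert rate == pytest.approx(oracle_rate, abs=0.03)


class TestScreenHrFixedSvs:
    @staticmethod
    def scenario(effect_log2fc=2.0, seed=0):
        """Six accessions (4 HR, 2 HS); one SV fixed in 3 HR accessions
        with a cis effect on its neighbouring gene; decoy SVs that fail the
        fixation rule."""
        rng = np.random.default_rng(seed)
        accs = [f"acc{i}" for i in range(1, 7)]
        hr, hs = accs[:4], accs[4:]
        genes = [GeneModel(gene_id=f"g{i}", chrom="chr1", start=i * 20_000,
                           end=i * 20_000 + 2_000, strand="+",
                           exons=[(i * 20_000, i * 20_000 + 2_000)])
                 for i in range(10)]
        records = [
            make_sv("PAV_del", 3_000, 4_000, sv_id="svFIX"),     # near g0
            make_sv("PAV_del", 23_000, 24_000, sv_id="svHS"),    # near g1
            make_sv("PAV_del", 43_000, 44_000, sv_id="svTWO"),   # near g2
        ]
        presence = pd.DataFrame(False, index=["svFIX", "svHS", "svTWO"],
                                columns=accs)
        presence.loc["svFIX", hr[:3]] = True                 # 3 HR, 0 HS
        presence.loc["svHS", hr[:3] + [hs[0]]] = True        # HS presence
        presence.loc["svTWO", hr[:2]] = True                 # only 2 HR
        carriers = hr[:3]
        samples, counts = [], []
        for acc in accs:
            for cond in ("control", "heat"):
                for rep in range(3):
                    samples.append({"sample": f"{acc}_{cond}_{rep}",
                                    "accession": acc, "tissue": "leaf",
                                    "condition": cond, "time": "1h",
                                    "replicate": rep})
                    mu = np.full(10, 200.0)
                    if acc in carriers:
                        mu[0] *= 2.0 ** effect_log2fc  # cis effect on g0
                    lam = rng.gamma(10.0, mu / 10.0)
                    counts.append(rng.poisson(lam))
        meta = pd.DataFrame(samples).set_index("sample")
        cdf = pd.DataFrame(np.array(counts).T,
                           index=[g.gene_id for g in genes],
                           columns=meta.index)
        lengths = pd.Series(1000.0, index=cdf.index)
        mat = ex.ExpressionMatrix(counts=cdf,
                                  tpm=ex.tpm_normalize(cdf, lengths),
                                  samples=meta, gene_lengths=lengths)
        return presence, records, hr, hs, genes, mat

    def test_fixation_rule_and_recovery(self):
        presence, records, hr, hs, genes, mat = self.scenario()
        res = ex.screen_hr_fixed_svs(presence, records, hr, hs, genes, mat,
                                     heat_responsive={"g0"})
        # stage 1 keeps only the truly fixed SV
        assert res.stage_counts["hr_fixed_svs"] == 1
        assert set(res.candidates["sv_id"]) == {"svFIX"}
        assert set(res.candidates["gene_id"]) == {"g0"}
        assert res.candidates["heat_responsive"].all()

    def test_stage_counts_non_increasing(self):
        presence, records, hr, hs, genes, mat = self.scenario()
        res = ex.screen_hr_fixed_svs(presence, records, hr, hs, genes, mat)
        sc = res.stage_counts
        assert sc["tested_pairs"] <= sc["sv_gene_pairs"]
        assert sc["significant_pairs"] <= sc["tested_pairs"]

    def test_null_effect_yields_no_candidates(self):
        presence, records, hr, hs, genes, mat = self.scenario(
            effect_log2fc=0.0, seed=3)
        res = ex.screen_hr_fixed_svs(presence, records, hr, hs, genes, mat)
        assert len(res.candidates) == 0

    def test_distance_rule(self):
        presence, records, hr, hs, genes, mat = self.scenario()
        res = ex.screen_hr_fixed_svs(presence, records, hr, hs, genes, mat,
                                     q_max=1.1)  # keep everything tested
        pairs = set(zip(res.candidates["sv_id"], res.candidates["gene_id"]))
        # svFIX spans [3000,4000): overlaps g0's flank only (gene at 0-2000)
        assert ("svFIX", "g0") in pairs
        assert all(g == "g0" for _, g in pairs)


class TestWilcoxonNullCalibration:
    def test_null_p_uniformity(self):
        """With no cis effects, per-pair rank-test p-values are uniform
        (24 vs 24 samples, 1,000 null genes)."""
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(1000):
            x = rng.normal(size=24)
            y = rng.normal(size=24)
            ps.append(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="asymptotic").pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
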