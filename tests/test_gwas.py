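import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petalgwas.datatypes import GeneModel
from petalgwas.gwas import (
    MixedModelGWAS,
    MlmNullFit,
    bonferroni_threshold,
    candidate_windows,
    estimate_n_independent,
    find_peaks,
    fit_null_mlm,
    imputed_dosages,
    mlm_scan,
    vanraden_kinship,
    _reml_loglik,
)
from petalgwas.simulate import PhenoSimConfig, PopSimConfig, simulate_genotypes, simulate_phenotypes

from conftest import make_matrix


def identity_null_fit(n, sigma2_e=1.0):
    """Null fit pinned at K = I with zero genetic variance."""
    return MlmNullFit(
        sigma2_g=0.0,
        sigma2_e=sigma2_e,
        reml_loglik=0.0,
        eigvals=np.ones(n),
        eigvecs=np.eye(n),
        X=np.ones((n, 1)),
    )


class TestKinship:
    def test_identical_rows_have_equal_self_and_cross_entry(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]])
        K = vanraden_kinship(make_matrix(calls))
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_symmetric_and_psd_on_panel(self, structured_panel):
        G, _ = structured_panel
        K = vanraden_kinship(G)
        assert np.allclose(K, K.T)
        evals = np.linalg.eigvalsh(K)
        assert evals.min() > -1e-8

    def test_matches_hand_arithmetic(self):
        calls = np.array(
            [[0, 1, 2, 0, 1, 2], [1, 1, 0, 2, 0, 1], [2, 0, 1, 1, 2, 0], [0, 2, 2, 0, 1, 1]]
        )
        G = make_matrix(calls)
        X = calls.astype(float)
        p = X.mean(axis=0) / 2
        W = X - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        assert np.allclose(vanraden_kinship(G), expected, atol=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            vanraden_kinship(make_matrix([[0, 1, 2]]))


class TestNullReml:
    def test_pure_noise_has_low_estimated_h2(self, gwas_panel):
        """Under an unstructured trait the REML h2 stays near zero."""
        G = gwas_panel
        K = vanraden_kinship(G)
        hits = 0
        for seed in range(10):
            y = np.random.default_rng(seed).standard_normal(G.n_samples)
            fit = fit_null_mlm(y, K)
            hits += fit.h2 < 0.15
        assert hits >= 9

    def test_polygenic_trait_recovers_high_h2(self):
        """h2 = 0.8 is recovered when the kinship spectrum is dispersed
        enough to identify the genetic variance (markers ~ samples)."""
        cfg = PopSimConfig(n_per_subpop=(100, 100, 100), n_variants=300, seed=7)
        G, _ = simulate_genotypes(cfg)
        K = vanraden_kinship(G)
        scale = np.sqrt(0.8 / np.diag(K).mean())
        w, U = np.linalg.eigh(K)
        L = U * np.sqrt(np.clip(w, 0, None))
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            u = scale * (L @ rng.standard_normal(G.n_samples))
            y = u + np.sqrt(0.2) * rng.standard_normal(G.n_samples)
            fit = fit_null_mlm(y, K)
            hits += 0.6 <= fit.h2 <= 0.95
        assert hits >= 9

    def test_optimum_beats_a_lambda_grid(self, clean_panel):
        G, _ = clean_panel
        K = vanraden_kinship(G)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(G.n_samples)
        fit = fit_null_mlm(y, K)

        n = G.n_samples
        X = np.ones((n, 1))
        S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        w_all, U_all = np.linalg.eigh(S @ (K + np.eye(n)) @ S)
        idx = np.argsort(w_all)[::-1][: n - 1]
        xi = np.clip(w_all[idx] - 1, 0, None)
        eta2 = (U_all[:, idx].T @ y) ** 2
        grid = np.logspace(-4, 4, 50)
        assert fit.reml_loglik >= max(_reml_loglik(d, xi, eta2) for d in grid) - 1e-6

    def test_nonfinite_phenotype_rejected(self, clean_panel):
        G, _ = clean_panel
        y = np.full(G.n_samples, np.nan)
        with pytest.raises(ValueError):
            fit_null_mlm(y, vanraden_kinship(G))


class TestScan:
    def test_reduces_to_ols_with_identity_kinship(self):
        cfg = PopSimConfig(n_per_subpop=(50, 50, 50), n_variants=300, seed=8)
        G, _ = simulate_genotypes(cfg)
        y = np.random.default_rng(1).standard_normal(150)
        assoc = mlm_scan(G, y, identity_null_fit(150))
        X = imputed_dosages(G)
        for j in range(0, 300, 23):
            ols = stats.linregress(X[:, j], y)
            assert assoc["p"][j] == pytest.approx(ols.pvalue, abs=1e-8)
            assert assoc["beta"][j] == pytest.approx(ols.slope, rel=1e-8)

    def test_null_pvalues_are_uniform_under_structure(self):
        """With the polygenic term matching K, scan p-values pass a KS test."""
        cfg = PopSimConfig(n_per_subpop=(100, 100, 100), n_variants=5000, seed=13)
        G, _ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(
            G, PhenoSimConfig(cross_trait_loading=0.0, seed=14)
        )
        res = MixedModelGWAS.from_dataframe(pheno, "vexil_area", G).fit()
        ks = stats.kstest(res.assoc["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_marker_gets_p_one(self):
        calls = np.zeros((30, 2), dtype=np.int8)
        calls[:15, 1] = 2
        G = make_matrix(calls)
        y = np.random.default_rng(0).standard_normal(30)
        assoc = mlm_scan(G, y, identity_null_fit(30))
        assert assoc["p"][0] == 1.0
        assert assoc["p"][1] < 1.0

    def test_scan_invariant_to_marker_order(self, clean_panel):
        G, _ = clean_panel
        rng = np.random.default_rng(2)
        y = rng.standard_normal(G.n_samples)
        fit = fit_null_mlm(y, vanraden_kinship(G))
        base = mlm_scan(G, y, fit)
        perm = rng.permutation(G.n_variants)
        shuffled = mlm_scan(G.take_variants(perm), y, fit)
        back = shuffled.set_index("id").loc[base["id"]]
        assert np.allclose(back["p"].to_numpy(), base["p"].to_numpy(), atol=1e-12)

    def test_neglog10p_consistent_with_p(self, clean_panel):
        G, _ = clean_panel
        y = np.random.default_rng(3).standard_normal(G.n_samples)
        assoc = mlm_scan(G, y, identity_null_fit(G.n_samples))
        assert np.allclose(assoc["neglog10p"], -np.log10(assoc["p"]), atol=1e-10)


class TestThreshold:
    @pytest.mark.parametrize(
        "n,expected", [(100, 4.0), (10**6, 8.0)]
    )
    def test_neglog10_thresholds(self, n, expected):
        thr = bonferroni_threshold(n, alpha=0.01)
        assert thr.neglog10_threshold == pytest.approx(expected, abs=1e-12)

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(100, alpha=1.0)

    def test_threshold_monotone_in_n(self):
        p1 = bonferroni_threshold(100).p_threshold
        p2 = bonferroni_threshold(1000).p_threshold
        assert p2 < p1

    def test_one_over_n_mode(self):
        thr = bonferroni_threshold(1000, mode="one_over_n")
        assert thr.p_threshold == pytest.approx(1e-3)

    def test_ld_pruning_estimate_bounds(self, clean_panel):
        G, _ = clean_panel
        n_ind = estimate_n_independent(G)
        assert 1 <= n_ind <= G.n_variants


class TestPeaksAndWindows:
    def _assoc(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "p"])
        df["beta"] = 1.0
        df["se"] = 0.1
        df["neglog10p"] = -np.log10(df["p"])
        return df[["chrom", "pos", "id", "beta", "se", "p", "neglog10p"]]

    def test_no_significant_variants_gives_empty(self):
        assoc = self._assoc([("c1", 100, "a", 0.5)])
        thr = bonferroni_threshold(100, 0.01)
        assert find_peaks(assoc, thr).empty

    def test_nearby_significant_variants_clump_to_one_peak(self):
        assoc = self._assoc([("c1", 100_000, "a", 1e-8), ("c1", 110_000, "b", 1e-6)])
        thr = bonferroni_threshold(100, 0.01)
        peaks = find_peaks(assoc, thr, clump_distance=500_000)
        assert len(peaks) == 1
        assert peaks["id"].iloc[0] == "a"
        assert peaks["n_clumped"].iloc[0] == 2

    def test_three_planted_regions_give_three_peaks(self):
        rows = []
        for k, center in enumerate([1_000_000, 5_000_000, 9_000_000]):
            for off in (-20_000, 0, 20_000):
                rows.append(("c1", center + off, f"v{k}_{off}", 1e-9 if off == 0 else 1e-7))
        rows.append(("c1", 3_000_000, "null", 0.3))
        thr = bonferroni_threshold(100, 0.01)
        peaks = find_peaks(self._assoc(rows), thr)
        assert sorted(peaks["pos"]) == [1_000_000, 5_000_000, 9_000_000]

    def test_paper_peak_window_bounds(self):
        """The +/-250 kb window around Chr07:41,489,216."""
        assoc = self._assoc([("Chr07", 41_489_216, "peak", 1e-12)])
        thr = bonferroni_threshold(100, 0.01)
        windows = candidate_windows(find_peaks(assoc, thr), [])
        assert windows[0].start == 41_239_216
        assert windows[0].end == 41_739_216

    def test_gene_touching_window_edge_included(self):
        assoc = self._assoc([("c1", 1_000_000, "peak", 1e-12)])
        thr = bonferroni_threshold(100, 0.01)
        genes = [
            GeneModel("edge", "c1", "+", (700_000, 750_000)),  # ends exactly at start
            GeneModel("out", "c1", "+", (600_000, 749_999)),
        ]
        w = candidate_windows(find_peaks(assoc, thr), genes)[0]
        assert w.start == 750_000
        assert w.gene_ids == ("edge",)

    def test_window_genes_match_brute_force(self):
        rng = np.random.default_rng(17)
        genes = []
        for i in range(7):
            lo = int(rng.integers(100_000, 2_000_000))
            genes.append(GeneModel(f"g{i}", "c1", "+", (lo, lo + 50_000)))
        assoc = self._assoc([("c1", 1_000_000, "peak", 1e-12)])
        thr = bonferroni_threshold(100, 0.01)
        w = candidate_windows(find_peaks(assoc, thr), genes)[0]
        expected = {
            g.gene_id
            for g in genes
            if g.gene_span[0] <= w.end and g.gene_span[1] >= w.start
        }
        assert set(w.gene_ids) == expected


class TestModelInterface:
    def test_planted_causal_snp_is_top_hit_nearby(self):
        """A 10%-variance causal SNP at n=309 tops its 50-kb neighborhood."""
        hits = 0
        for seed in range(3):
            cfg = PopSimConfig(n_variants=1500, pos_step=1000, seed=30 + seed)
            G, _ = simulate_genotypes(cfg)
            causal_id = G.variants["id"].iloc[750]
            beta = np.sqrt(0.10 / 0.90)
            pheno, _ = simulate_phenotypes(
                G,
                PhenoSimConfig(
                    causal_variants={causal_id: beta},
                    h2_poly=0.3,
                    cross_trait_loading=0.0,
                    noise_sd=np.sqrt(0.7),
                    seed=60 + seed,
                ),
            )
            res = MixedModelGWAS.from_dataframe(pheno, "vexil_area", G).fit()
            top = res.assoc.loc[res.assoc["p"].idxmin()]
            causal_pos = G.variants["pos"].iloc[750]
            hits += abs(top["pos"] - causal_pos) <= 50_000
        assert hits >= 2

    def test_from_dataframe_drops_missing_trait_values(self, clean_panel):
        G, _ = clean_panel
        pheno = pd.DataFrame(
            {"t": np.random.default_rng(0).standard_normal(G.n_samples)},
            index=G.samples,
        )
        pheno.iloc[:5, 0] = np.nan
        model = MixedModelGWAS.from_dataframe(pheno, "t", G)
        assert model.G.n_samples == G.n_samples - 5

    def test_summary_mentions_key_quantities(self, clean_panel):
        G, _ = clean_panel
        y = np.random.default_rng(1).standard_normal(G.n_samples)
        res = MixedModelGWAS(y, G).fit()
        res.threshold(n_independent=400)
        text = res.summary()
        assert "sigma2_g" in text and "threshold" in text

    def test_qq_data_is_monotone(self, clean_panel):
        G, _ = clean_panel
        y = np.random.default_rng(2).standard_normal(G.n_samples)
        qq = MixedModelGWAS(y, G).fit().qq_data()
        assert (np.diff(qq["expected_neglog10p"]) <= 0).all()
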