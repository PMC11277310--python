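import math

import numpy as np
import pytest

from petalgwas.datatypes import MISSING
from petalgwas.popgen import (
    GenomicWindow,
    make_windows,
    pairwise_ld,
    sample_heterozygosity,
    tajima_constants,
    tajima_d,
    window_fst,
    window_pi,
    window_tajima_d,
)

from conftest import make_matrix


def one_window(chrom="Chr01", start=1, width=20_000):
    return [GenomicWindow(chrom, start, start + width - 1)]


class TestWindowPi:
    def test_single_site_unbiased_estimator(self):
        """Two diploids coded (0,2): pi = (4/3) * 2 * 0.5 * 0.5."""
        G = make_matrix([[0], [2]])
        out = window_pi(G, one_window())
        assert out["value"].iloc[0] * 20_000 == pytest.approx(4 / 3 * 0.5, abs=1e-12)
        assert out["n_sites"].iloc[0] == 1

    def test_window_value_scales_by_width(self):
        G = make_matrix([[0], [2]])
        out = window_pi(G, one_window())
        assert out["value"].iloc[0] == pytest.approx(0.6667 / 20_000, rel=1e-3)

    def test_monomorphic_window_is_zero(self):
        G = make_matrix(np.zeros((4, 5)))
        assert window_pi(G, one_window())["value"].iloc[0] == 0.0

    def test_matches_brute_force_pairwise_differences(self):
        """Unbiased per-site pi equals the mean pairwise difference over all
        allele pairs, computed by enumeration."""
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(6, 8)).astype(np.int8)
        G = make_matrix(calls)
        total = 0.0
        for j in range(8):
            alleles = []
            for c in calls[:, j]:
                alleles += [1] * int(c) + [0] * (2 - int(c))
            diffs = sum(
                a != b
                for i, a in enumerate(alleles)
                for b in alleles[i + 1:]
            )
            n_pairs = len(alleles) * (len(alleles) - 1) / 2
            total += diffs / n_pairs
        out = window_pi(G, one_window())
        assert out["value"].iloc[0] * 20_000 == pytest.approx(total, abs=1e-10)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        G = make_matrix(calls)
        perm = rng.permutation(10)
        G2 = G.take_samples(perm)
        v1 = window_pi(G, one_window())["value"]
        v2 = window_pi(G2, one_window())["value"]
        assert np.allclose(v1, v2)

    def test_invariant_to_allele_relabeling(self):
        calls = np.array([[0, 1], [2, 1], [1, 0], [0, 2]], dtype=np.int8)
        flipped = (2 - calls).astype(np.int8)
        v1 = window_pi(make_matrix(calls), one_window())["value"]
        v2 = window_pi(make_matrix(flipped), one_window())["value"]
        assert np.allclose(v1, v2)


class TestWindowFst:
    def test_complete_fixation_gives_one(self):
        calls = np.vstack([np.zeros((6, 4)), np.full((6, 4), 2)]).astype(np.int8)
        G = make_matrix(calls)
        labels = np.array([0] * 6 + [1] * 6)
        out = window_fst(G, labels, one_window())
        assert out["value"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_panmictic_split_is_near_zero(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.9, size=2000)
        calls = rng.binomial(2, p, size=(80, 2000)).astype(np.int8)
        G = make_matrix(calls, step=10)
        labels = rng.permutation(np.array([0] * 40 + [1] * 40))
        out = window_fst(G, labels, one_window())
        assert abs(out["value"].iloc[0]) < 0.01

    def test_matches_hand_evaluated_weir_cockerham(self):
        """3-site, 2-pop example against an independent per-site W&C
        evaluation written out longhand."""
        calls = np.array(
            [
                [0, 1, 2],
                [1, 1, 0],
                [2, 0, 0],
                [0, 2, 1],
                [2, 2, 2],
                [1, 2, 1],
                [2, 1, 2],
                [2, 2, 1],
            ],
            dtype=np.int8,
        )
        G = make_matrix(calls)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])

        def wc_site(col):
            r = 2
            groups = [col[:4], col[4:]]
            n_i = np.array([4.0, 4.0])
            p_i = np.array([g.sum() / (2 * len(g)) for g in groups])
            h_i = np.array([(g == 1).mean() for g in groups])
            nbar = 4.0
            nc = (8 - (16 + 16) / 8) / (r - 1)
            pbar = (n_i * p_i).sum() / 8
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / 8
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2
            return a, a + b + c

        num = den = 0.0
        for j in range(3):
            a, tot = wc_site(calls[:, j].astype(float))
            num += a
            den += tot
        out = window_fst(G, labels, one_window())
        assert out["value"].iloc[0] == pytest.approx(num / den, abs=1e-10)

    def test_fst_windows_advance_by_2kb(self):
        windows = make_windows("c", (1, 10_000), width=20_000, step=2_000)
        starts = [w.start for w in windows]
        assert starts == [1, 2001, 4001, 6001, 8001]

    def test_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        labels = np.array([0] * 10 + [1] * 10)
        v1 = window_fst(make_matrix(calls), labels, one_window())["value"]
        v2 = window_fst(make_matrix((2 - calls).astype(np.int8)), labels, one_window())["value"]
        assert np.allclose(v1, v2)


class TestTajimaD:
    def test_zero_when_pi_equals_watterson(self):
        """If pi_total = S/a1 the numerator vanishes."""
        k = tajima_constants(10)
        S = 5
        assert tajima_d(S / k["a1"], S, 10) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_excess_is_negative(self):
        # 10 haplotypes = 5 diploids; each of 10 sites has one het (singleton)
        calls = np.zeros((5, 10), dtype=np.int8)
        for j in range(10):
            calls[j % 5, j] = 1
        G = make_matrix(calls)
        out = window_tajima_d(G, one_window())
        assert out["value"].iloc[0] < 0

    def test_matches_independent_constants_evaluation(self):
        """5-site window against a from-scratch evaluation of the 1989
        normalization constants."""
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(5, 5)).astype(np.int8)  # n = 10 haplotypes
        G = make_matrix(calls)
        out = window_tajima_d(G, one_window())

        n = 10
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        p = calls.sum(axis=0) / n
        seg = (p > 0) & (p < 1)
        S = int(seg.sum())
        pi_total = float((n / (n - 1) * 2 * p * (1 - p))[seg].sum())
        expected = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert out["value"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_no_segregating_sites_flagged(self):
        G = make_matrix(np.zeros((5, 3)))
        out = window_tajima_d(G, one_window())
        assert math.isnan(out["value"].iloc[0])
        assert out["n_sites"].iloc[0] == 0


class TestHeterozygosity:
    def test_all_het_sample_counts_every_site(self):
        calls = np.ones((3, 50), dtype=np.int8)
        calls[0] = np.tile([0, 2], 25)  # keep sites polymorphic
        out = sample_heterozygosity(make_matrix(calls))
        assert out.loc[out["sample"] == "S001", "obs_het"].iloc[0] == 50

    def test_f_zero_when_observed_matches_expected(self):
        # alternating hom patterns give obs het = exp het at p = 0.5 sites
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.5, size=(200, 300)).astype(np.int8)
        out = sample_heterozygosity(make_matrix(calls))
        assert abs(out["F"].mean()) < 0.05

    def test_matches_direct_count(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        G = make_matrix(calls)
        out = sample_heterozygosity(G)
        p, an = [], []
        obs_mat = calls != MISSING
        for j in range(40):
            col = calls[:, j]
            o = col[col != MISSING]
            an.append(2 * o.size)
            p.append(o.sum() / (2 * o.size) if o.size else np.nan)
        for i in range(8):
            expected_obs = sum(
                1
                for j in range(40)
                if calls[i, j] == 1 and an[j] >= 4
            )
            assert out["obs_het"].iloc[i] == expected_obs


class TestPairwiseLd:
    def test_identical_columns_have_full_ld(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=30).astype(np.int8)
        G = make_matrix(np.stack([col, col], axis=1))
        out = pairwise_ld(G)
        assert out["r2"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert out["d_prime"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_code_swapped_copy_keeps_r2(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=30).astype(np.int8)
        G = make_matrix(np.stack([col, (2 - col).astype(np.int8)], axis=1))
        out = pairwise_ld(G)
        assert out["r2"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_em_recovers_phased_truth(self):
        """Haplotypes drawn with known frequencies; EM frequency estimates
        sit close to the counted truth."""
        rng = np.random.default_rng(9)
        freqs = np.array([0.5, 0.2, 0.1, 0.2])  # 00, 01, 10, 11
        haps = rng.choice(4, size=(400, 2), p=freqs)  # two haplotypes per sample

        def hap_to_alleles(h):
            return np.stack([(h >= 2).astype(int), (h % 2)], axis=-1)

        alleles = hap_to_alleles(haps)  # (n, 2 haps, 2 loci)
        calls = alleles.sum(axis=1).astype(np.int8)
        counted = np.bincount(haps.ravel(), minlength=4) / haps.size
        G = make_matrix(calls)
        out = pairwise_ld(G)
        est = out[["f_rr", "f_ra", "f_ar", "f_aa"]].iloc[0].to_numpy()
        assert np.allclose(est, counted, atol=0.01)
        assert abs(est.sum() - 1) < 1e-9

    def test_monomorphic_pair_skipped(self):
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:5, 1] = 2
        with pytest.raises(ValueError):
            pairwise_ld(make_matrix(calls[:, :1]))
        out = pairwise_ld(make_matrix(calls))
        assert out.empty  # column 0 monomorphic -> no valid pair


class TestDivergenceLadder:
    def test_mean_fst_monotone_in_simulated_divergence(self):
        from petalgwas.simulate import PopSimConfig, simulate_genotypes

        means = []
        for F in (0.05, 0.15, 0.30):
            cfg = PopSimConfig(
                n_per_subpop=(40, 40, 40), n_variants=800, divergence=(F, F, F), seed=2
            )
            G, labels = simulate_genotypes(cfg)
            w = make_windows("Chr07", (41_000_000, 41_800_000), 20_000)
            out = window_fst(G, labels, w)
            means.append(out["value"].mean())
        assert means[0] < means[1] < means[2]
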