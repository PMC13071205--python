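"""Multiple-testing corrections, PhenoSpD Meff, top-k and gene windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectragwas import simulate as sim
from spectragwas.posthoc import (bh_fdr, candidate_genes, direct_correlation,
                                 ld_scores, meff, phenospd_correlation,
                                 significance_threshold, top_k_dynamic)


def toy_genotypes(dosages, pos=None, chrom=None):
    d = np.asarray(dosages, dtype=np.int8)
    m = d.shape[1]
    return sim.GenotypeMatrix(
        dosages=d,
        samples=[f"s{i}" for i in range(d.shape[0])],
        chrom=np.asarray(chrom) if chrom is not None else np.ones(m, int),
        pos=np.asarray(pos) if pos is not None else np.arange(1, m + 1),
    )


class TestLdScores:
    def test_independent_snps_near_noise_floor(self):
        rng = np.random.default_rng(0)
        n, m = 100, 200
        g = toy_genotypes(rng.binomial(2, 0.4, size=(n, m)))
        scores = ld_scores(g, window_bp=10**9)
        # E[r^2] = 1/(n-1) for independent SNPs; self contributes 1
        expected = 1 + (m - 1) / (n - 1)
        se = scores.std(ddof=1) / np.sqrt(m)
        assert abs(scores.mean() - expected) < 3 * se + 0.05

    def test_perfectly_correlated_pair_scores_two(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        g = toy_genotypes(np.column_stack([col, col]), pos=[100, 200])
        scores = ld_scores(g, window_bp=1000)
        assert np.allclose(scores.values, 2.0)

    def test_zero_window_scores_one(self):
        rng = np.random.default_rng(1)
        g = toy_genotypes(rng.binomial(2, 0.5, size=(30, 10)))
        assert np.allclose(ld_scores(g, window_bp=0).values, 1.0)

    def test_single_snp_chromosome(self):
        col = np.array([0, 1, 2, 1], dtype=np.int8)
        g = toy_genotypes(col[:, None], pos=[5], chrom=[3])
        assert ld_scores(g).iloc[0] == pytest.approx(1.0)


class TestPhenoSpD:
    def test_duplicated_trait_intercept_near_one(self):
        rng = np.random.default_rng(2)
        m = 10_000
        z = rng.normal(size=m)
        zs = pd.DataFrame({"t1": z, "t2": z})
        ld = pd.Series(np.full(m, 1.0) + rng.uniform(0, 0.01, m),
                       index=zs.index)
        C = phenospd_correlation(zs, ld)
        assert C.iloc[0, 1] == pytest.approx(1.0, abs=0.1)

    def test_independent_null_traits_intercept_near_zero(self):
        rng = np.random.default_rng(3)
        m = 10_000
        zs = pd.DataFrame({"t1": rng.normal(size=m), "t2": rng.normal(size=m)})
        ld = pd.Series(rng.uniform(1, 3, m), index=zs.index)
        C = phenospd_correlation(zs, ld)
        # intercept SE ~ sqrt(var(Z1 Z2)/m) = 1/100 at leverage ~ a few
        assert abs(C.iloc[0, 1]) < 3 * 0.03

    def test_direct_mode_agrees_on_unstructured_data(self):
        rng = np.random.default_rng(4)
        n, m = 200, 2000
        g = toy_genotypes(rng.binomial(2, 0.3, size=(n, m)))
        rho = 0.6
        f = rng.normal(size=n)
        y1 = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
        y2 = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
        from spectragwas.gwas import glm_scan

        z1 = glm_scan(y1, g)["stat"]
        z2 = glm_scan(y2, g)["stat"]
        zs = pd.DataFrame({"t1": z1.values, "t2": z2.values},
                          index=g.snp_ids)
        ld = ld_scores(g, window_bp=10**9)
        C_ldsc = phenospd_correlation(zs, ld)
        C_direct = direct_correlation(pd.DataFrame({"t1": y1, "t2": y2}))
        assert C_ldsc.iloc[0, 1] == pytest.approx(C_direct.iloc[0, 1],
                                                  abs=0.15)

    def test_constant_ld_falls_back_with_warning(self):
        rng = np.random.default_rng(5)
        zs = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        ld = pd.Series(np.ones(100), index=zs.index)
        with pytest.warns(UserWarning, match="constant LD"):
            phenospd_correlation(zs, ld)

    def test_too_few_snps_raises(self):
        zs = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            phenospd_correlation(zs, pd.Series(np.ones(10), index=zs.index))


class TestMeff:
    def test_identity_gives_m(self):
        for M in (2, 6, 20):
            assert meff(np.eye(M)) == pytest.approx(M)

    def test_all_ones_gives_one(self):
        for M in (2, 6, 20):
            assert meff(np.ones((M, M))) == pytest.approx(1.0)

    def test_closed_form_two_by_two(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])  # eigenvalues 1.5, 0.5
        assert meff(C) == pytest.approx(4.0 / 2.5)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_bounds_on_random_psd(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.integers(2, 10)
        A = rng.normal(size=(M, M + 3))
        C = np.corrcoef(A)
        m = meff(C)
        assert 1.0 - 1e-9 <= m <= M + 1e-9

    def test_alternative_methods_run(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert meff(C, method="nyholt") == pytest.approx(1.75)
        assert 1.0 <= meff(C, method="liji") <= 2.0


class TestThreshold:
    def test_printed_values(self):
        assert significance_threshold(5.0) == pytest.approx(0.01)
        assert significance_threshold(999.9) == pytest.approx(5.0e-5, rel=5e-3)
        assert significance_threshold(1.0) == pytest.approx(0.05)

    def test_meff_below_one_raises(self):
        with pytest.raises(ValueError):
            significance_threshold(0.5)


def brute_force_bh(p):
    """Step-up oracle computed literally from the definition."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestBhFdr:
    def test_hand_computed_example(self):
        adj = bh_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    @given(seed=st.integers(0, 10_000), m=st.integers(1, 20))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed, m):
        p = np.random.default_rng(seed).uniform(1e-6, 1.0, size=m)
        assert np.allclose(bh_fdr(p), brute_force_bh(p))

    def test_adjusted_at_least_raw_and_monotone(self):
        p = np.random.default_rng(7).uniform(size=50)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_empty_input(self):
        assert len(bh_fdr(np.array([]))) == 0


def results_frame(snps, pvals, phenotype, chrom=None, pos=None):
    m = len(snps)
    return pd.DataFrame({
        "snp": snps,
        "chrom": chrom if chrom is not None else np.ones(m, int),
        "pos": pos if pos is not None else np.arange(1, m + 1),
        "effect": 0.0, "se": 1.0, "stat": 0.0,
        "p": pvals, "model": "GLM", "phenotype": phenotype,
    })


class TestTopKDynamic:
    def test_k_one_threshold_is_global_min(self):
        res = results_frame([f"chr1_{i}" for i in range(1, 6)],
                            [0.5, 0.01, 0.2, 0.9, 0.3], "a")
        ranking, thr, passing = top_k_dynamic(res, k=1)
        assert thr == 0.01
        assert set(passing["snp"]) == {"chr1_2"}

    def test_stripe_snp_contributes_all_phenotype_hits(self):
        frames = []
        for i, ph in enumerate(f"ph{j}" for j in range(10)):
            pv = np.full(60, 0.5)
            pv[0] = 1e-6  # one SNP hits all 10 phenotypes
            frames.append(results_frame(
                [f"chr1_{k}" for k in range(1, 61)], pv, ph))
        ranking, thr, passing = top_k_dynamic(frames, k=50)
        stripe = passing[passing["snp"] == "chr1_1"]
        assert len(stripe) == 10

    def test_overlap_arithmetic(self):
        # two methods sharing 42 of their top-50 SNP ids overlap by 84%
        top_a = {f"chr1_{i}" for i in range(50)}
        top_b = {f"chr1_{i}" for i in range(8, 58)}
        overlap = 100 * len(top_a & top_b) / 50
        assert overlap == 84.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(8)
        res = results_frame([f"chr1_{i}" for i in range(1, 201)],
                            rng.uniform(size=200), "a")
        counts = [len(top_k_dynamic(res, k=k)[2]) for k in (10, 50, 100)]
        assert counts == sorted(counts)

    def test_k_too_large_raises(self):
        res = results_frame(["chr1_1", "chr1_2"], [0.1, 0.2], "a")
        with pytest.raises(ValueError):
            top_k_dynamic(res, k=3)


GFF_HEADER = "##gff-version 3\n"


def write_gff(path, genes):
    lines = [GFF_HEADER]
    for gid, chrom, start, end in genes:
        lines.append(
            f"{chrom}\tsrc\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")
    path.write_text("".join(lines))


class TestCandidateGenes:
    def test_inclusive_boundary_arithmetic(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        write_gff(gff, [("g1", "chr1", 200_001, 210_000)])
        out = candidate_genes(["chr1_100000"], gff, window_bp=100_000)
        assert len(out) == 0  # window ends at 200,000 < gene start
        out = candidate_genes(["chr1_100001"], gff, window_bp=100_000)
        assert list(out["gene_id"]) == ["g1"]

    def test_snp_inside_gene_distance_zero(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        write_gff(gff, [("g1", "chr2", 1000, 2000)])
        out = candidate_genes(["chr2_1500"], gff, window_bp=100)
        assert out["distance"].iloc[0] == 0

    def test_matches_brute_force_interval_oracle(self, tmp_path):
        genes = [("g1", "chr1", 100, 500), ("g2", "chr1", 9_000, 9_500),
                 ("g3", "chr1", 10_400, 11_000), ("g4", "chr1", 12_000, 12_100),
                 ("g5", "chr1", 50_000, 51_000)]
        gff = tmp_path / "five.gff3"
        write_gff(gff, genes)
        snp_pos, window = 10_000, 1_500
        out = candidate_genes([f"chr1_{snp_pos}"], gff, window_bp=window)
        brute = {g for g, c, s, e in genes
                 if e >= snp_pos - window and s <= snp_pos + window}
        assert set(out["gene_id"]) == brute == {"g2", "g3"}

    def test_whitelist_filters(self, tmp_path):
        gff = tmp_path / "wl.gff3"
        write_gff(gff, [("g1", "chr1", 900, 1100), ("g2", "chr1", 950, 1050)])
        out = candidate_genes(["chr1_1000"], gff, window_bp=100,
                              whitelist=["g2"])
        assert list(out["gene_id"]) == ["g2"]

    def test_unknown_chromosome_warns_and_skips(self, tmp_path):
        gff = tmp_path / "u.gff3"
        write_gff(gff, [("g1", "chr1", 900, 1100)])
        with pytest.warns(UserWarning, match="unknown chromosome"):
            out = candidate_genes(["chr9_1000"], gff, window_bp=100)
        assert len(out) == 0


def test_significance_call_rule():
    # an association is significant iff its BH-adjusted p < alpha / Meff
    p = np.array([1e-8, 1e-4, 0.02, 0.5])
    adj = bh_fdr(p)
    thr = significance_threshold(5.0)  # 0.01
    assert list(adj < thr) == [True, True, False, False]
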