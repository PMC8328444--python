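"""Genotype-likelihood model, EM allele frequencies, LRTs and filters."""

import numpy as np
import pytest

import lcpanel as lp
from conftest import certain_gl, make_filter_toy
from lcpanel.likelihoods import (_hwe_weights, _loglik, _maf_em_batch,
                                 estimate_maf_em, genotype_likelihoods,
                                 hwe_lrt, posterior_genotypes, snp_lrt)
from lcpanel.synthetic import ReadCountMatrix


def reads_from_counts(pairs):
    """(a, b) pairs for one site -> ReadCountMatrix of shape (1, n, 2)."""
    return ReadCountMatrix(np.asarray(pairs, dtype=np.int32)[None, :, :])


class TestGenotypeLikelihoods:
    def test_known_values_five_major_reads(self):
        gl = genotype_likelihoods(reads_from_counts([(5, 0)]), eps=0.01)
        raw = np.array([0.99 ** 5, 0.5 ** 5, 0.01 ** 5])
        np.testing.assert_allclose(gl.values[0, 0], raw / raw.sum(), rtol=1e-10)

    def test_balanced_reads_symmetric(self, rng):
        for depth in (1, 3, 10, 200):
            gl = genotype_likelihoods(reads_from_counts([(depth, depth)]), 0.05)
            assert gl.values[0, 0, 0] == pytest.approx(gl.values[0, 0, 2])

    def test_zero_depth_uniform_and_missing(self):
        gl = genotype_likelihoods(reads_from_counts([(0, 0), (2, 1)]), 0.01)
        assert gl.missing[0, 0] and not gl.missing[0, 1]
        np.testing.assert_allclose(gl.values[0, 0], [1 / 3] * 3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            genotype_likelihoods(reads_from_counts([(1, 1)]), eps=0.6)
        bad = ReadCountMatrix.__new__(ReadCountMatrix)
        bad.counts = np.array([[[-1, 2]]])
        with pytest.raises(ValueError):
            genotype_likelihoods(bad, 0.01)

    def test_deep_coverage_does_not_underflow(self):
        gl = genotype_likelihoods(reads_from_counts([(5000, 4)]), 0.01)
        assert np.isfinite(gl.values).all()
        assert gl.values[0, 0, 0] > 0.99


class TestMafEm:
    def test_all_hom_major_gives_zero(self):
        g = np.zeros((1, 30), dtype=np.int8)
        gl = certain_gl(g)
        assert estimate_maf_em(gl.values[0]) == pytest.approx(0.0, abs=1e-6)

    def test_all_het_gives_half(self):
        g = np.ones((1, 50), dtype=np.int8)
        gl = certain_gl(g)
        assert estimate_maf_em(gl.values[0]) == pytest.approx(0.5, abs=1e-6)

    def test_infinite_coverage_equals_sample_frequency(self, rng):
        g = rng.binomial(2, 0.37, size=(1, 80)).astype(np.int8)
        gl = certain_gl(g, eps=1e-12)
        truth = g.sum() / 160
        est = estimate_maf_em(gl.values[0])
        assert est == pytest.approx(min(truth, 1 - truth), abs=1e-6)

    def test_low_coverage_near_genotype_frequency(self, rng):
        cfg = lp.SimConfig(error_rate=0.01)
        g = rng.binomial(2, 0.2, size=(1, 100)).astype(np.int8)
        reads = lp.simulate_reads(g, cfg, rng, coverage=np.full(100, 20.0))
        gl = genotype_likelihoods(reads, 0.01)
        truth = min(g.mean() / 2, 1 - g.mean() / 2)
        assert estimate_maf_em(gl.values[0], gl.missing[0]) == pytest.approx(
            truth, abs=0.05
        )

    def test_all_missing_site_raises(self):
        vals = np.full((3, 3), 1 / 3)
        with pytest.raises(ValueError, match="no individual"):
            estimate_maf_em(vals, missing=np.ones(3, bool))

    def test_em_loglik_nondecreasing(self, rng):
        """The EM objective never decreases across iterations."""
        for _ in range(5):
            v = rng.random((1, 25, 3))
            v /= v.sum(axis=2, keepdims=True)
            miss = np.zeros((1, 25), bool)
            f = np.array([0.25])
            prev = _loglik(v, miss, f)[0]
            for _ in range(30):
                w = _hwe_weights(f)
                post = v * w[:, None, :]
                post /= post.sum(axis=2, keepdims=True)
                f = np.array([(post[0, :, 1] + 2 * post[0, :, 2]).sum() / 50])
                cur = _loglik(v, miss, f)[0]
                assert cur >= prev - 1e-9
                prev = cur


class TestSnpLrt:
    def test_monomorphic_site_stat_zero(self):
        g = np.zeros((1, 40), dtype=np.int8)
        stat, p = snp_lrt(certain_gl(g).values[0])
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_many_hets_overwhelmingly_polymorphic(self):
        g = np.ones((1, 150), dtype=np.int8)
        _, p = snp_lrt(certain_gl(g, eps=1e-6).values[0])
        assert p < 1e-6

    def test_invariant_to_allele_relabeling(self, rng):
        v = rng.random((20, 3))
        v /= v.sum(axis=1, keepdims=True)
        stat1, _ = snp_lrt(v)
        stat2, _ = snp_lrt(v[:, ::-1])
        assert stat1 == pytest.approx(stat2, abs=1e-6)


class TestHweLrt:
    def test_hwe_proportions_not_rejected(self):
        g = np.repeat([0, 1, 2], [25, 50, 25]).astype(np.int8)[None, :]
        F, stat, p = hwe_lrt(certain_gl(g).values[0])
        assert abs(F) < 0.02
        assert p > 0.5

    def test_all_het_strongly_rejected(self):
        g = np.ones((1, 100), dtype=np.int8)
        F, stat, p = hwe_lrt(certain_gl(g, eps=1e-6).values[0])
        assert F < -0.95  # at the lower feasibility bound
        assert p < 1e-6

    def test_invariant_to_allele_relabeling(self, rng):
        v = rng.random((30, 3))
        v /= v.sum(axis=1, keepdims=True)
        _, stat1, _ = hwe_lrt(v)
        _, stat2, _ = hwe_lrt(v[:, ::-1])
        assert stat1 == pytest.approx(stat2, abs=1e-3)


class TestFilters:
    def test_engineered_toy_retains_exactly_one(self):
        reads, site_info, thresholds, expected_fail = make_filter_toy()
        gl, sites = lp.call_snps(reads, site_info, 0.01, thresholds)
        flag_cols = ["pass_depth", "pass_ind", "pass_maf", "pass_snp",
                     "pass_hwe"]
        for i, fail_col in enumerate(expected_fail):
            for col in flag_cols:
                should_pass = col != fail_col
                assert bool(sites.loc[i, col]) == should_pass, (
                    f"site {i}: {col} expected {should_pass}"
                )
        assert sites["retained"].sum() == 1
        assert sites.loc[6, "retained"]

    def test_filter_order_irrelevant(self):
        """Flags are independent functions of the statistics, so the
        retained set equals the conjunction in any order."""
        reads, site_info, thresholds, _ = make_filter_toy()
        _, sites = lp.call_snps(reads, site_info, 0.01, thresholds)
        conj = np.ones(len(sites), bool)
        for col in ["pass_hwe", "pass_snp", "pass_maf", "pass_ind",
                    "pass_depth"]:
            conj &= sites[col].to_numpy()
        np.testing.assert_array_equal(conj, sites["retained"].to_numpy())

    def test_min_ind_scales_with_sample_size(self):
        t = lp.FilterThresholds()
        assert t.resolved_min_ind(222) == 150
        assert t.resolved_min_ind(100) == 68
        assert lp.FilterThresholds(min_ind=150).resolved_min_ind(30) == 150


class TestPosteriorGenotypes:
    def test_certain_het_ignores_prior(self):
        gl = lp.GenotypeLikelihoodMatrix(
            np.array([[[0.0, 1.0, 0.0]]]), np.zeros((1, 1), bool)
        )
        dosage, hard, _ = posterior_genotypes(gl, np.array([0.01]))
        assert dosage[0, 0] == pytest.approx(1.0)
        assert hard[0, 0] == 1

    def test_uniform_triple_returns_prior(self):
        gl = lp.GenotypeLikelihoodMatrix(
            np.full((1, 1, 3), 1 / 3), np.ones((1, 1), bool)
        )
        dosage, hard, missing = posterior_genotypes(gl, np.array([0.1]))
        np.testing.assert_allclose(dosage[0, 0], 0.18 + 2 * 0.01, atol=1e-12)
        assert hard[0, 0] == -1  # missing stays missing
        assert missing[0, 0]

    def test_deep_coverage_hard_calls_match_truth(self, rng):
        cfg = lp.SimConfig(error_rate=0.01)
        g = rng.binomial(2, 0.3, size=(200, 40)).astype(np.int8)
        reads = lp.simulate_reads(g, cfg, rng, coverage=np.full(40, 30.0))
        gl = genotype_likelihoods(reads, 0.01)
        f = _maf_em_batch(gl.values, gl.missing)
        _, hard, miss = posterior_genotypes(gl, f)
        ok = ~miss
        assert (hard[ok] == g[ok]).mean() >= 0.99


def test_pvalues_in_unit_interval(small_dataset):
    *_, sites = small_dataset
    for col in ("snp_p", "hwe_p"):
        vals = sites[col].dropna().to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
    stats = sites["snp_stat"].dropna().to_numpy()
    assert (stats >= -1e-9).all()
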