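"""SAF dynamic program, SFS EM, per-site components, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lcpanel.fst as F
from conftest import brute_force_saf, certain_gl
from lcpanel.io_formats import CongruenceError


def normalized_triples(rng, n):
    v = rng.random((n, 3))
    return v / v.sum(axis=1, keepdims=True)


class TestSafLikelihoods:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 3), st.integers(0, 2 ** 31 - 1))
    def test_dp_equals_brute_force(self, n, seed):
        """The DP marginalization reproduces exhaustive enumeration over
        all 3^n genotype configurations to 1e-12."""
        triples = normalized_triples(np.random.default_rng(seed), n)
        dp = F.saf_likelihoods(triples[None])[0]
        oracle = brute_force_saf(triples)
        np.testing.assert_allclose(dp, oracle, atol=1e-12)

    def test_two_certain_hets_force_j_two(self):
        triples = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        saf = F.saf_likelihoods(triples[None])[0]
        assert saf[2] == 1.0
        assert saf[[0, 1, 3, 4]].max() == 0.0

    def test_vector_length(self, rng):
        for n in (1, 4, 9):
            saf = F.saf_likelihoods(normalized_triples(rng, n)[None])
            assert saf.shape == (1, 2 * n + 1)

    def test_missing_individuals_keep_length(self, rng):
        triples = normalized_triples(rng, 4)
        triples[2] = 1 / 3  # uniform = missing
        assert F.saf_likelihoods(triples[None]).shape == (1, 9)


class TestSfsEm:
    def test_certain_singletons_concentrate(self):
        g = np.zeros((200, 10), dtype=np.int8)
        g[:, 0] = 1  # every site has exactly one het copy
        saf = F.saf_likelihoods(certain_gl(g, eps=1e-12).values)
        sfs = F.estimate_sfs_em(saf)
        assert sfs[1] >= 0.999

    def test_infinite_coverage_matches_histogram(self, rng):
        g = rng.binomial(2, rng.uniform(0.05, 0.5, size=300)[:, None],
                         size=(300, 12)).astype(np.int8)
        saf = F.saf_likelihoods(certain_gl(g, eps=1e-12).values)
        sfs = F.estimate_sfs_em(saf)
        hist = np.bincount(g.sum(axis=1), minlength=25) / 300
        np.testing.assert_allclose(sfs, hist, atol=1e-4)

    def test_em_objective_nondecreasing(self, rng):
        saf = F.saf_likelihoods(
            np.stack([normalized_triples(rng, 6) for _ in range(40)])
        )
        p = np.full(13, 1 / 13)
        prev = -np.inf
        for _ in range(50):
            ll = np.log(np.maximum(saf @ p, 1e-300)).sum()
            assert ll >= prev - 1e-9
            prev = ll
            w = saf * p
            w /= w.sum(axis=1, keepdims=True)
            p = w.mean(axis=0)

    def test_folding_collapses_support(self, rng):
        saf = F.saf_likelihoods(
            np.stack([normalized_triples(rng, 5) for _ in range(30)])
        )
        sfs = F.estimate_sfs_em(saf, folded=True)
        assert len(sfs) == 6  # n + 1 classes after folding
        assert sfs.sum() == pytest.approx(1.0)


class TestSfs2d:
    def test_independent_populations_near_outer_product(self, rng):
        g1 = rng.binomial(2, rng.uniform(0.1, 0.5, 12000)[:, None], (12000, 4))
        g2 = rng.binomial(2, rng.uniform(0.1, 0.5, 12000)[:, None], (12000, 4))
        saf1 = F.saf_likelihoods(certain_gl(g1.astype(np.int8)).values)
        saf2 = F.saf_likelihoods(certain_gl(g2.astype(np.int8)).values)
        joint = F.estimate_2dsfs_em(saf1, saf2)
        m1 = F.estimate_sfs_em(saf1)
        m2 = F.estimate_sfs_em(saf2)
        assert 0.5 * np.abs(joint - np.outer(m1, m2)).sum() < 0.05
        # marginals agree with the 1D spectra
        assert np.abs(joint.sum(axis=1) - m1).sum() < 0.02
        assert np.abs(joint.sum(axis=0) - m2).sum() < 0.02
        assert joint.sum() == pytest.approx(1.0)
        assert (joint >= 0).all()

    def test_site_count_mismatch_raises(self, rng):
        saf1 = F.saf_likelihoods(
            np.stack([normalized_triples(rng, 3) for _ in range(5)])
        )
        saf2 = F.saf_likelihoods(
            np.stack([normalized_triples(rng, 3) for _ in range(4)])
        )
        with pytest.raises(CongruenceError):
            F.estimate_2dsfs_em(saf1, saf2)


class TestPersiteFst:
    def test_fixed_difference_approaches_one(self):
        n = 40
        g1 = np.zeros((50, n), dtype=np.int8)
        g2 = np.full((50, n), 2, dtype=np.int8)
        saf1 = F.saf_likelihoods(certain_gl(g1, eps=1e-12).values)
        saf2 = F.saf_likelihoods(certain_gl(g2, eps=1e-12).values)
        sfs = F.estimate_2dsfs_em(saf1, saf2)
        a, b = F.persite_fst(saf1, saf2, sfs)
        assert (a / b > 0.99).all()

    def test_equal_frequencies_give_nonpositive_a(self):
        g = np.tile(np.array([0, 1, 2, 1, 0, 1, 2, 1], dtype=np.int8), (30, 1))
        saf1 = F.saf_likelihoods(certain_gl(g, eps=1e-12).values)
        sfs = F.estimate_2dsfs_em(saf1, saf1)
        a, b = F.persite_fst(saf1, saf1, sfs)
        assert (a <= 1e-9).all()
        assert (b > 0).all()

    def test_certain_data_matches_plugin_formulas(self, rng):
        n1, n2 = 12, 9
        g1 = rng.binomial(2, 0.3, (40, n1)).astype(np.int8)
        g2 = rng.binomial(2, 0.6, (40, n2)).astype(np.int8)
        saf1 = F.saf_likelihoods(certain_gl(g1, eps=1e-12).values)
        saf2 = F.saf_likelihoods(certain_gl(g2, eps=1e-12).values)
        sfs = F.estimate_2dsfs_em(saf1, saf2)
        a, b = F.persite_fst(saf1, saf2, sfs)
        p1 = g1.sum(axis=1) / (2 * n1)
        p2 = g2.sum(axis=1) / (2 * n2)
        a_plug = ((p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1)
                  - p2 * (1 - p2) / (2 * n2 - 1))
        b_plug = p1 * (1 - p2) + p2 * (1 - p1)
        np.testing.assert_allclose(a, a_plug, atol=1e-6)
        np.testing.assert_allclose(b, b_plug, atol=1e-6)


class TestGlobalWeighted:
    def test_identical_components_give_ratio(self):
        a = np.full(10, 0.02)
        b = np.full(10, 0.2)
        assert F.global_weighted_fst(a, b) == pytest.approx(0.1)

    def test_invariant_to_reordering(self, rng):
        a, b = rng.normal(0.01, 0.02, 50), rng.uniform(0.1, 0.5, 50)
        perm = rng.permutation(50)
        assert F.global_weighted_fst(a, b) == pytest.approx(
            F.global_weighted_fst(a[perm], b[perm])
        )

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            F.global_weighted_fst(np.array([0.1]), np.array([0.0]))


class TestSlidingWindows:
    def test_tiling_when_step_equals_window(self):
        comp = pd.DataFrame(
            {"chrom": "LG01", "pos": [50, 150, 1040, 2900],
             "a": 0.1, "b": 1.0}
        )
        win = F.sliding_window_fst(comp, win_bp=1000, step_bp=1000)
        assert win["n_sites"].sum() == 4  # every site in exactly one window

    def test_single_site_appears_in_six_windows(self):
        comp = pd.DataFrame(
            {"chrom": ["LG01"], "pos": [550], "a": [0.05], "b": [0.5]}
        )
        win = F.sliding_window_fst(comp, win_bp=1000, step_bp=100)
        assert len(win) == 6
        assert list(win["start"]) == [1, 101, 201, 301, 401, 501]
        np.testing.assert_allclose(win["fst"], 0.1)

    def test_block_windows_stand_out(self, small_dataset):
        cfg, reads, genotypes, truth, site_info, gl, sites = small_dataset
        ret = sites["retained"].to_numpy()
        glr = gl.subset_sites(ret)
        pop = truth.individuals["population"].to_numpy()
        saf1 = F.saf_likelihoods(glr.values[:, pop == 0, :])
        saf2 = F.saf_likelihoods(glr.values[:, pop == 1, :])
        sfs = F.estimate_2dsfs_em(saf1, saf2)
        a, b = F.persite_fst(saf1, saf2, sfs)
        comp = sites.loc[ret, ["chrom", "pos"]].reset_index(drop=True)
        comp["a"], comp["b"] = a, b
        win = F.sliding_window_fst(comp, win_bp=20_000, step_bp=5_000)
        lo, hi = cfg.block_span_bp
        block_chrom = cfg.chrom_names()[cfg.block_chrom]
        in_block = ((win["chrom"] == block_chrom)
                    & (win["start"] >= lo - 20_000) & (win["end"] <= hi + 20_000))
        assert win.loc[in_block, "fst"].median() > \
            10 * abs(win.loc[~in_block, "fst"].median())

    def test_unsorted_input_rejected(self):
        comp = pd.DataFrame(
            {"chrom": "LG01", "pos": [500, 100], "a": 0.1, "b": 1.0}
        )
        with pytest.raises(CongruenceError):
            F.sliding_window_fst(comp)


def test_split_half_fst_is_null(rng):
    """Two halves of one panmictic population show |FST| < 0.01."""
    import lcpanel as lp
    from lcpanel.likelihoods import genotype_likelihoods
    from lcpanel.validation import gl_weighted_fst

    cfg = lp.SimConfig(n_pop1=30, n_pop2=30, n_chrom=1, sites_per_chrom=2000,
                       chrom_length_bp=10 ** 7, baseline_fst=0.0,
                       n_block_sites=0, n_minor_peaks=0, n_sex_sites=0,
                       block_chrom=0, sex_region_chrom=0,
                       coverage_range=(10, 10), seed=21)
    reads, g, truth, site_info = lp.simulate_dataset(cfg)
    gl = genotype_likelihoods(reads, cfg.error_rate)
    split = np.zeros(60, bool)
    split[:30] = True
    assert abs(gl_weighted_fst(gl.values, split)) < 0.01
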