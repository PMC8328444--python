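"""Shared fixtures: small simulated datasets and oracle helpers."""

import itertools
from math import comb

import numpy as np
import pytest

import lcpanel as lp


def brute_force_saf(triples: np.ndarray) -> np.ndarray:
    """Independent SAF oracle: enumerate every genotype configuration.

    For n individuals with likelihood triples L_i, sums
    prod_i L_i(g_i) * C(2, g_i) over all configurations with sum g_i = j,
    divides by C(2n, j) (multivariate hypergeometric normalization) and
    max-scales — the definition the DP must reproduce.
    """
    triples = np.asarray(triples, dtype=float)
    n = triples.shape[0]
    out = np.zeros(2 * n + 1)
    for config in itertools.product(range(3), repeat=n):
        j = sum(config)
        w = 1.0
        for i, g in enumerate(config):
            w *= triples[i, g] * comb(2, g)
        out[j] += w
    out /= np.array([comb(2 * n, j) for j in range(2 * n + 1)])
    return out / out.max()


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of
    # which tests ran before it
    return np.random.default_rng(20231109)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-population dataset with a block, peaks and sex sites,
    called end to end: (reads, genotypes, truth, site_info, gl, sites)."""
    cfg = lp.SimConfig(
        n_pop1=30, n_pop2=30, n_chrom=2, sites_per_chrom=150,
        chrom_length_bp=500_000, block_chrom=0,
        block_span_bp=(200_000, 300_000), n_block_sites=15,
        sex_region_chrom=1, sex_region_span_bp=(100_000, 150_000),
        n_sex_sites=10, n_minor_peaks=3, coverage_range=(2.0, 4.0), seed=6,
    )
    reads, genotypes, truth, site_info = lp.simulate_dataset(cfg)
    gl, sites = lp.call_snps(reads, site_info, cfg.error_rate)
    return cfg, reads, genotypes, truth, site_info, gl, sites


def make_filter_toy():
    """Seven engineered sites over 20 individuals, each of six failing
    exactly one retention criterion, plus one passing all of them.

    Thresholds: total depth in [14, 400], >=6 individuals with data,
    MAF >= 0.05, polymorphism p < 1e-4, HWE-departure p <= 1e-4 removed.
    Returns (reads, site_info, thresholds, expected_fail_column).
    """
    import pandas as pd

    import lcpanel as lp
    from lcpanel.likelihoods import FilterThresholds

    N = 20
    counts = np.zeros((7, N, 2), dtype=np.int32)
    # site 0: total depth 12 < 14 (six heterozygous individuals, 2 reads each)
    counts[0, :6] = [1, 1]
    # site 1: total depth 420 > 400, otherwise healthy HWE mix
    counts[1, :11] = [21, 0]
    counts[1, 11:19] = [11, 10]
    counts[1, 19] = [0, 21]
    # site 2: only 5 individuals with data (< 6)
    counts[2, :3] = [6, 0]
    counts[2, 3:5] = [3, 3]
    # site 3: MAF ~ 1/40 < 0.05 (one certain het among 19 hom-major)
    counts[3, :19] = [10, 0]
    counts[3, 19] = [5, 5]
    # site 4: weak polymorphism evidence (single reads; p > 1e-4)
    counts[4, :17] = [1, 0]
    counts[4, 17:] = [0, 1]
    # site 5: extreme heterozygote excess fails HWE
    counts[5, :] = [5, 5]
    # site 6: passes everything (HWE mix at MAF 0.25)
    counts[6, :11] = [10, 0]
    counts[6, 11:19] = [5, 5]
    counts[6, 19] = [0, 10]
    reads = lp.ReadCountMatrix(counts)
    site_info = pd.DataFrame(
        {"chrom": ["LG01"] * 7, "pos": (np.arange(7) + 1) * 100,
         "allele1": 0, "allele2": 1}
    )
    thresholds = FilterThresholds(min_depth=14, max_depth=400, min_ind=6,
                                  min_maf=0.05, snp_alpha=1e-4,
                                  hwe_alpha=1e-4)
    expected_fail = ["pass_depth", "pass_depth", "pass_ind", "pass_maf",
                     "pass_snp", "pass_hwe", None]
    return reads, site_info, thresholds, expected_fail


def certain_gl(genotypes: np.ndarray, eps: float = 1e-9):
    """Likelihood triples that pin each genotype (near-infinite coverage)."""
    S, N = genotypes.shape
    values = np.full((S, N, 3), eps)
    for g in range(3):
        mask = genotypes == g
        values[:, :, g][mask] = 1.0 - 2 * eps
    return lp.GenotypeLikelihoodMatrix(values, np.zeros((S, N), dtype=bool))
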