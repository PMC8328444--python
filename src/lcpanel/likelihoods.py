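"""Genotype likelihoods, allele-frequency estimation and SNP filtering.

Reads are summarised per individual-site as counts (a, b) of the two
alleles. Under a symmetric two-allele error model with error rate eps
(a misread base reports the other allele), the genotype likelihoods for
g = 0, 1, 2 copies of allele2 are

    L(0) = (1-eps)^a eps^b,   L(1) = 0.5^(a+b),   L(2) = eps^a (1-eps)^b,

normalized to sum 1. Zero depth yields the uniform triple and a missing
flag. This collapsed error model matches the simulator's read model (sites
are biallelic by construction); it deviates from 4-base mixture models on
purpose, and the single eps also stands in for a base-quality floor since
no per-base qualities exist here.

The minor allele frequency is the maximum-likelihood frequency under
Hardy-Weinberg, found by EM over individuals; polymorphism and
Hardy-Weinberg departure are likelihood-ratio tests against chi2(1).
Retention filters mirror standard lcWGS practice: total depth bounds,
minimum individuals with data, MAF floor, SNP p-value ceiling and HWE
p-value floor, each flagged independently so filter order is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeLikelihoodMatrix
from .synthetic import ReadCountMatrix

__all__ = [
    "FilterThresholds",
    "genotype_likelihoods",
    "estimate_maf_em",
    "snp_lrt",
    "hwe_lrt",
    "call_snps",
    "filter_sites",
    "posterior_genotypes",
]

_EM_TOL = 1e-6
_EM_MAX_ITER = 200


@dataclass
class FilterThresholds:
    """SNP retention thresholds.

    Defaults follow common lcWGS practice at full study scale (total depth
    in [50, 500], at least 150-of-222 individuals with data, MAF >= 5%,
    polymorphism p < 1e-6 required, HWE-departure p <= 1e-6 removed).
    ``min_ind=None`` scales the individuals threshold with sample size as
    ceil(N * 150/222) so small simulations are not auto-emptied; pass an
    absolute value to reproduce full-scale behavior.
    """

    min_depth: int = 50
    max_depth: int = 500
    min_ind: int | None = None
    min_maf: float = 0.05
    snp_alpha: float = 1e-6
    hwe_alpha: float = 1e-6

    def resolved_min_ind(self, n_ind: int) -> int:
        if self.min_ind is not None:
            return self.min_ind
        return math.ceil(n_ind * 150.0 / 222.0)


def genotype_likelihoods(reads: ReadCountMatrix, eps: float) -> GenotypeLikelihoodMatrix:
    """Per-site, per-individual likelihood triples from allele read counts.

    Triple order is (hom allele1, het, hom allele2); normalization is done
    in log space so high depths cannot underflow.
    """
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must be in (0, 0.5)")
    counts = reads.counts
    if (counts < 0).any():
        raise ValueError("negative read counts")
    a = counts[:, :, 0].astype(float)
    b = counts[:, :, 1].astype(float)
    log_l = np.stack(
        [
            a * math.log1p(-eps) + b * math.log(eps),
            (a + b) * math.log(0.5),
            a * math.log(eps) + b * math.log1p(-eps),
        ],
        axis=2,
    )
    log_l -= log_l.max(axis=2, keepdims=True)
    l = np.exp(log_l)
    l /= l.sum(axis=2, keepdims=True)
    missing = (a + b) == 0
    l[missing] = 1.0 / 3.0
    return GenotypeLikelihoodMatrix(l, missing)


def _hwe_weights(f, F=None):
    """HWE genotype priors, optionally with inbreeding coefficient F."""
    f = np.asarray(f, dtype=float)
    if F is None:
        return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)
    F = np.asarray(F, dtype=float)
    c = f * (1 - f) * F
    return np.stack(
        [(1 - f) ** 2 + c, 2 * f * (1 - f) * (1 - F), f ** 2 + c], axis=-1
    )


def _loglik(values, missing, f, F=None):
    """Sum over non-missing individuals of log sum_g L(g) w_g. Shapes:
    values (S, N, 3), f (S,) -> (S,)."""
    w = _hwe_weights(f, F)  # (S, 3)
    per_ind = np.einsum("sng,sg->sn", values, w)
    per_ind = np.where(missing, 1.0, per_ind)
    return np.log(np.maximum(per_ind, 1e-300)).sum(axis=1)


def _maf_em_batch(values, missing, tol=_EM_TOL, max_iter=_EM_MAX_ITER):
    """EM allele-2 frequency per site; all-missing sites come back NaN."""
    S, N, _ = values.shape
    n_obs = (~missing).sum(axis=1).astype(float)
    f = np.full(S, 0.2)
    ok = n_obs > 0
    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        w = _hwe_weights(f[active])
        post = values[active] * w[:, None, :]
        post /= np.maximum(post.sum(axis=2, keepdims=True), 1e-300)
        eg = post[:, :, 1] + 2.0 * post[:, :, 2]
        eg[missing[active]] = 0.0
        f_new = eg.sum(axis=1) / (2.0 * n_obs[active])
        delta = np.abs(f_new - f[active])
        f[active] = f_new
        still = np.zeros(S, dtype=bool)
        still[np.flatnonzero(active)[delta >= tol]] = True
        active = still
    f[~ok] = np.nan
    return f


def estimate_maf_em(gl_site: np.ndarray, missing=None) -> float:
    """Minor allele frequency at one site by EM under Hardy-Weinberg.

    ``gl_site`` is (n_ind, 3); returns min(f, 1-f) after polarization.
    Raises on an all-missing site.
    """
    gl_site = np.asarray(gl_site, dtype=float)[None]
    if missing is None:
        missing = np.zeros(gl_site.shape[:2], dtype=bool)
    else:
        missing = np.asarray(missing, dtype=bool)[None]
    if missing.all():
        raise ValueError("allele frequency undefined: no individual has data")
    f = _maf_em_batch(gl_site, missing)[0]
    return float(min(f, 1.0 - f))


def _snp_lrt_batch(values, missing, f):
    """Polymorphism LRT per site: 2[l(f_hat) - l(monomorphic)] vs chi2(1).

    The null is the better of the two fixed states (f = 0 or f = 1), which
    is its MLE and makes the statistic invariant to allele relabeling.
    """
    S = values.shape[0]
    ll_hat = _loglik(values, missing, f)
    ll0 = _loglik(values, missing, np.zeros(S))
    ll1 = _loglik(values, missing, np.ones(S))
    stat = 2.0 * (ll_hat - np.maximum(ll0, ll1))
    stat = np.maximum(stat, 0.0)
    p = stats.chi2.sf(stat, df=1)
    return stat, p


def snp_lrt(gl_site: np.ndarray, missing=None):
    """Polymorphism test at one site; returns (statistic, p)."""
    gl_site = np.asarray(gl_site, dtype=float)
    if missing is None:
        missing = np.zeros(len(gl_site), dtype=bool)
    missing = np.asarray(missing, bool)
    # the EM frequency in the site's own orientation (not minor-polarized)
    f = _maf_em_batch(gl_site[None], missing[None])
    stat, p = _snp_lrt_batch(gl_site[None], missing[None], f)
    return float(stat[0]), float(p[0])


def _hwe_bounds(f):
    lo = np.maximum(-f / np.maximum(1 - f, 1e-12), -(1 - f) / np.maximum(f, 1e-12))
    return np.clip(lo, -1.0, 0.0), np.ones_like(f)


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _hwe_lrt_batch(values, missing, f, grid_step=0.01, refine_iter=24):
    """HWE-departure LRT per site, profiling the inbreeding coefficient F.

    f is held at its EM estimate; F is maximized on its feasible interval
    by a coarse grid then golden-section refinement. LRT vs F=0, chi2(1).
    """
    S = values.shape[0]
    f = np.clip(f, 1e-9, 1 - 1e-9)
    lo, hi = _hwe_bounds(f)
    grid = np.arange(-1.0, 1.0 + grid_step / 2, grid_step)
    best_ll = np.full(S, -np.inf)
    best_F = np.zeros(S)
    for F in grid:
        feasible = (F >= lo) & (F <= hi)
        if not feasible.any():
            continue
        ll = _loglik(values, missing, f, np.full(S, F))
        upd = feasible & (ll > best_ll)
        best_ll[upd] = ll[upd]
        best_F[upd] = F
    a = np.maximum(best_F - grid_step, lo)
    b = np.minimum(best_F + grid_step, hi)
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1 = _loglik(values, missing, f, x1)
    f2 = _loglik(values, missing, f, x2)
    for _ in range(refine_iter):
        take_left = f1 >= f2
        b = np.where(take_left, x2, b)
        a = np.where(take_left, a, x1)
        x1 = b - _GOLDEN * (b - a)
        x2 = a + _GOLDEN * (b - a)
        f1 = _loglik(values, missing, f, x1)
        f2 = _loglik(values, missing, f, x2)
    F_hat = np.where(f1 >= f2, x1, x2)
    ll_alt = np.maximum(np.maximum(f1, f2), best_ll)
    ll_null = _loglik(values, missing, f, np.zeros(S))
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(stat, df=1)
    return F_hat, stat, p


def hwe_lrt(gl_site: np.ndarray, missing=None):
    """HWE test at one site; returns (F_hat, statistic, p)."""
    gl_site = np.asarray(gl_site, dtype=float)
    if missing is None:
        missing = np.zeros(len(gl_site), dtype=bool)
    missing = np.asarray(missing, bool)
    f = _maf_em_batch(gl_site[None], missing[None])[0]
    F, stat, p = _hwe_lrt_batch(gl_site[None], missing[None], np.array([f]))
    return float(F[0]), float(stat[0]), float(p[0])


def call_snps(reads: ReadCountMatrix, site_info: pd.DataFrame, eps: float,
              thresholds: FilterThresholds | None = None):
    """Full SNP-calling pass: likelihoods, MAF, tests, polarization, flags.

    ``site_info`` needs columns chrom, pos, allele1, allele2. Returns
    ``(gl, sites)`` where ``gl`` is minor-polarized (triples ordered hom
    major / het / hom minor) over ALL sites and ``sites`` carries every
    per-site statistic plus independent filter flags and ``retained``.
    Subset with ``gl.subset_sites(sites["retained"].to_numpy())``.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    gl = genotype_likelihoods(reads, eps)
    depth = reads.depth
    total_depth = depth.sum(axis=1)
    n_ind_with_data = (depth > 0).sum(axis=1)

    f2 = _maf_em_batch(gl.values, gl.missing)
    # polarize: major = more frequent allele; ties toward smaller base code
    a1 = site_info["allele1"].to_numpy()
    a2 = site_info["allele2"].to_numpy()
    f2_safe = np.nan_to_num(f2, nan=0.0)
    flip = (f2_safe > 0.5) | ((f2_safe == 0.5) & (a2 < a1))
    values = gl.values.copy()
    values[flip] = values[flip][:, :, ::-1]
    gl = GenotypeLikelihoodMatrix(values, gl.missing.copy())
    major = np.where(flip, a2, a1)
    minor = np.where(flip, a1, a2)
    maf = np.where(flip, 1.0 - f2, f2)

    valid = ~np.isnan(maf)
    snp_stat = np.full(len(maf), np.nan)
    snp_p = np.full(len(maf), np.nan)
    hwe_F = np.full(len(maf), np.nan)
    hwe_p = np.full(len(maf), np.nan)
    if valid.any():
        sub_v, sub_m, sub_f = gl.values[valid], gl.missing[valid], maf[valid]
        snp_stat[valid], snp_p[valid] = _snp_lrt_batch(sub_v, sub_m, sub_f)
        hwe_F[valid], _, hwe_p[valid] = _hwe_lrt_batch(sub_v, sub_m, sub_f)

    sites = pd.DataFrame(
        {
            "chrom": site_info["chrom"].to_numpy(),
            "pos": site_info["pos"].to_numpy(),
            "major": major,
            "minor": minor,
            "maf": maf,
            "n_ind_with_data": n_ind_with_data,
            "total_depth": total_depth,
            "snp_stat": snp_stat,
            "snp_p": snp_p,
            "hwe_F": hwe_F,
            "hwe_p": hwe_p,
        }
    )
    sites = filter_sites(sites, thresholds, n_ind=gl.n_ind)
    return gl, sites


def filter_sites(sites: pd.DataFrame, thresholds: FilterThresholds,
                 n_ind: int | None = None) -> pd.DataFrame:
    """Attach one boolean flag per retention criterion plus ``retained``.

    Each flag is a pure function of the stored statistics, so applying the
    filters in any order gives the same retained set.
    """
    if n_ind is None:
        n_ind = int(sites["n_ind_with_data"].max())
    min_ind = thresholds.resolved_min_ind(n_ind)
    out = sites.copy()
    depth = out["total_depth"].to_numpy()
    maf = out["maf"].to_numpy()
    out["pass_depth"] = (depth >= thresholds.min_depth) & (depth <= thresholds.max_depth)
    out["pass_ind"] = out["n_ind_with_data"].to_numpy() >= min_ind
    out["pass_maf"] = np.nan_to_num(maf, nan=-1.0) >= thresholds.min_maf
    out["pass_snp"] = np.nan_to_num(out["snp_p"].to_numpy(), nan=1.0) < thresholds.snp_alpha
    out["pass_hwe"] = np.nan_to_num(out["hwe_p"].to_numpy(), nan=1.0) > thresholds.hwe_alpha
    out["retained"] = (
        out["pass_depth"] & out["pass_ind"] & out["pass_maf"]
        & out["pass_snp"] & out["pass_hwe"]
    )
    return out


def posterior_genotypes(gl: GenotypeLikelihoodMatrix, maf: np.ndarray):
    """Genotype posteriors under a per-site Hardy-Weinberg prior.

    Returns ``(dosage, hard_call, missing)``: expected minor-allele count
    E[g], the MAP genotype in {0,1,2} (-1 at missing entries), and the
    missing mask carried through unchanged.
    """
    maf = np.asarray(maf, dtype=float)
    w = _hwe_weights(np.clip(maf, 0.0, 1.0))  # (S, 3)
    post = gl.values * w[:, None, :]
    post /= np.maximum(post.sum(axis=2, keepdims=True), 1e-300)
    dosage = post[:, :, 1] + 2.0 * post[:, :, 2]
    hard = post.argmax(axis=2).astype(np.int8)
    hard[gl.missing] = -1
    return dosage, hard, gl.missing.copy()
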