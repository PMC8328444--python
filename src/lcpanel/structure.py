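"""Population structure from genotype likelihoods and a selection scan.

Principal components are computed without calling genotypes. Starting from
the global minor allele frequency f_s at every site, the algorithm iterates
(1) expected minor-allele dosages E[g_is] under each individual's current
allele-frequency prior pi_is, (2) the standardized covariance between
individuals

    C_ij = (1/S) sum_s (E[g_is] - 2 f_s)(E[g_js] - 2 f_s) / (2 f_s (1 - f_s)),

with the diagonal using E[g^2] so self-covariance is not understated, and
(3) a rank-K update of the individual allele frequencies from the top-K
eigenvectors, truncated away from 0 and 1 — until the frequencies stop
moving. Standardization always uses the global 2f(1-f) (not the evolving
pi), which is the stabler choice at low coverage.

The selection scan regresses each site's expected dosages on the top-K
eigenvectors, forms the K-vector of regression z-scores, and tests its
Mahalanobis distance (with the z covariance estimated over all sites)
against chi-squared with K degrees of freedom, after dividing by the
genomic-inflation factor lambda = median(d) / chi2_median(K). Significance
is assessed against a Bonferroni threshold alpha / n_sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenotypeLikelihoodMatrix
from .likelihoods import _hwe_weights

__all__ = [
    "CovarianceResult",
    "ScanResult",
    "gl_covariance",
    "pcadapt_scan",
    "bonferroni_threshold",
]


@dataclass
class CovarianceResult:
    cov: np.ndarray          # (N, N) symmetric covariance between individuals
    pi: np.ndarray           # (N, S) individual allele frequencies
    eigenvalues: np.ndarray  # all N, sorted descending
    eigenvectors: np.ndarray # (N, N), columns matching eigenvalues
    k_used: int
    n_iter: int

    @property
    def pc_scores(self) -> np.ndarray:
        """(N, k_used) scores: eigenvectors scaled by sqrt(eigenvalue)."""
        lam = np.sqrt(np.maximum(self.eigenvalues[: self.k_used], 0.0))
        return self.eigenvectors[:, : self.k_used] * lam

    @property
    def variance_explained(self) -> np.ndarray:
        lam = np.maximum(self.eigenvalues, 0.0)
        total = lam.sum()
        return lam / total if total > 0 else lam


@dataclass
class ScanResult:
    stat: np.ndarray      # per-site Mahalanobis distance / lambda
    p: np.ndarray         # upper-tail chi2(K) p-values
    lambda_gc: float
    k: int
    bonferroni: float


def _expected_dosage(values: np.ndarray, pi: np.ndarray):
    """E[g] and E[g^2] per (individual, site) under priors HWE(pi).

    values is (S, N, 3); pi is (N, S). Returns arrays of shape (N, S).
    """
    w = _hwe_weights(pi.T)               # (S, N, 3)
    post = values * w
    post /= np.maximum(post.sum(axis=2, keepdims=True), 1e-300)
    eg = post[:, :, 1] + 2.0 * post[:, :, 2]
    eg2 = post[:, :, 1] + 4.0 * post[:, :, 2]
    return eg.T, eg2.T


def gl_covariance(gl: GenotypeLikelihoodMatrix, maf: np.ndarray, k: int = 2,
                  tol: float = 1e-4, max_iter: int = 100) -> CovarianceResult:
    """Iterative individual-allele-frequency covariance from likelihoods."""
    values = gl.values
    S, N, _ = values.shape
    if S == 0:
        raise ValueError("no retained sites")
    if not (1 <= k < N):
        raise ValueError(f"k must satisfy 1 <= k < {N}")
    f = np.clip(np.asarray(maf, dtype=float), 1e-6, 1 - 1e-6)
    denom = 2.0 * f * (1.0 - f)                      # (S,)
    lo, hi = 1.0 / (2 * N), 1.0 - 1.0 / (2 * N)

    pi = np.broadcast_to(f, (N, S)).copy()
    cov = np.zeros((N, N))
    eigvals = np.zeros(N)
    eigvecs = np.eye(N)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eg, eg2 = _expected_dosage(values, pi)       # (N, S)
        # center by the GLOBAL frequency: the individual frequencies only
        # sharpen the dosage priors — centering by 2*pi would subtract the
        # structure being estimated
        d = (eg - 2.0 * f) / np.sqrt(denom)
        cov = d @ d.T / S
        diag = ((eg2 - 4.0 * f * eg + 4.0 * f ** 2) / denom).mean(axis=1)
        np.fill_diagonal(cov, diag)
        eigvals, eigvecs = np.linalg.eigh(cov)
        eigvals = eigvals[::-1]
        eigvecs = eigvecs[:, ::-1]
        v = eigvecs[:, :k]
        centered = eg - 2.0 * f
        pi_new = np.clip((v @ (v.T @ centered) + 2.0 * f) / 2.0, lo, hi)
        delta = np.abs(pi_new - pi).max()
        pi = pi_new
        if delta < tol:
            break
    return CovarianceResult(cov, pi, eigvals, eigvecs, k, n_iter)


def pcadapt_scan(cov: CovarianceResult, gl: GenotypeLikelihoodMatrix,
                 maf: np.ndarray, alpha: float = 0.05) -> ScanResult:
    """Component-association outlier scan with genomic control.

    Per site: regress centered expected dosages on the top-K eigenvectors
    (orthonormal, so coefficients are inner products), scale by the
    residual standard deviation to get a z-vector, then the robustified
    Mahalanobis statistic d_s = z' Sigma^-1 z with Sigma estimated across
    sites. p-values are upper-tail chi2(K) of d_s / lambda_gc.
    """
    k = cov.k_used
    if k < 1:
        raise ValueError("need k >= 1")
    N, S = cov.pi.shape
    eg, _ = _expected_dosage(gl.values, cov.pi)      # (N, S)
    d = eg - eg.mean(axis=0)                         # center per site
    v = cov.eigenvectors[:, :k]                      # (N, k)
    beta = v.T @ d                                   # (k, S)
    resid = d - v @ beta
    dof = max(N - k - 1, 1)
    sigma = np.sqrt(np.maximum((resid ** 2).sum(axis=0) / dof, 1e-12))
    z = beta / sigma                                 # (k, S)
    # center z across sites: systematic per-individual offsets (coverage,
    # missingness) give the z components a nonzero genome-wide mean that is
    # not a selection signal
    zc = z - z.mean(axis=1, keepdims=True)
    sig_hat = np.atleast_2d(np.cov(z))
    try:
        sig_inv = np.linalg.inv(sig_hat)
    except np.linalg.LinAlgError:
        warnings.warn("singular z covariance; regularizing with 1e-8 I")
        sig_inv = np.linalg.inv(sig_hat + 1e-8 * np.eye(k))
    dist = np.einsum("ks,kl,ls->s", zc, sig_inv, zc)
    lambda_gc = float(np.median(dist) / stats.chi2.ppf(0.5, df=k))
    p = stats.chi2.sf(dist / lambda_gc, df=k)
    return ScanResult(dist / lambda_gc, p, lambda_gc, k,
                      bonferroni_threshold(alpha, S))


def bonferroni_threshold(alpha: float, n_sites: int) -> float:
    """Family-wise significance threshold alpha / n_sites."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return alpha / n_sites
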