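"""Sample allele frequency likelihoods, SFS estimation and FST.

The low-coverage route to FST never calls genotypes. Per population and
site, a dynamic program marginalizes individual genotype likelihoods into a
*sample allele frequency* (SAF) likelihood vector over j = 0..2n copies of
the minor allele:

    h_n(j)  proportional to  [sum over genotype configs with sum g_i = j of
            prod_i L_i(g_i) * C(2, g_i)] / C(2n, j)

(the binomial weights and the C(2n, j) denominator together form the
multivariate hypergeometric probability of a genotype configuration given
j minor alleles in the sample — without the denominator the vector is
tilted toward mid-frequency classes and the downstream spectra collapse
onto a central blob). The
1D and 2D site frequency spectra are then maximum-likelihood mixtures over
frequency classes, fitted by EM, and per-site FST components are posterior
expectations, under the 2D SFS prior, of the Hudson/Bhatia estimator's
numerator and denominator evaluated at sample frequencies p1 = j/2n1,
p2 = k/2n2:

    a(j,k) = (p1-p2)^2 - p1(1-p1)/(2n1-1) - p2(1-p2)/(2n2-1)
    b(j,k) = p1(1-p2) + p2(1-p1)

The global weighted FST is the ratio of sums sum_s a_s / sum_s b_s, and
sliding windows report the same ratio over the sites each window contains.
The Hudson/Bhatia components are used (rather than Reynolds) because they
are robust to unequal sample sizes; a genotype-based version of the same
estimator, :func:`hudson_fst_genotypes`, serves as the high-coverage
cross-check.

Missing individuals contribute the uniform triple to the SAF rather than
shrinking n, which keeps all vectors the same length across sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import CongruenceError

__all__ = [
    "saf_likelihoods",
    "estimate_sfs_em",
    "estimate_2dsfs_em",
    "fold_saf",
    "persite_fst",
    "global_weighted_fst",
    "sliding_window_fst",
    "hudson_fst_genotypes",
]

_W = np.array([1.0, 2.0, 1.0])  # C(2, g) diploid sampling weights


def saf_likelihoods(gl_values: np.ndarray) -> np.ndarray:
    """SAF likelihood vectors for one population.

    Parameters
    ----------
    gl_values : ndarray (n_sites, n_ind, 3)
        Minor-polarized likelihood triples (missing = uniform triple).

    Returns
    -------
    ndarray (n_sites, 2n+1), each row max-scaled to 1.
    """
    gl_values = np.asarray(gl_values, dtype=float)
    if gl_values.ndim == 2:  # single site convenience
        gl_values = gl_values[None]
    S, n, _ = gl_values.shape
    if n < 1:
        raise ValueError("need at least one individual")
    h = np.zeros((S, 2 * n + 1))
    h[:, 0] = 1.0
    width = 0
    for i in range(n):
        w = gl_values[:, i, :] * _W  # (S, 3)
        new = np.zeros_like(h)
        new[:, : width + 1] += h[:, : width + 1] * w[:, 0:1]
        new[:, 1 : width + 2] += h[:, : width + 1] * w[:, 1:2]
        new[:, 2 : width + 3] += h[:, : width + 1] * w[:, 2:3]
        width += 2
        scale = new[:, : width + 1].max(axis=1, keepdims=True)
        h = new / np.maximum(scale, 1e-300)
    # the configuration sum counts the C(2n, j) ways of placing j minor
    # alleles; divide it out so h(j) is proportional to P(reads | j)
    zero = h <= 0
    log_comb = (gammaln(2 * n + 1) - gammaln(np.arange(2 * n + 1) + 1)
                - gammaln(2 * n - np.arange(2 * n + 1) + 1))
    h = np.exp(np.log(np.maximum(h, 1e-300)) - log_comb)
    h[zero] = 0.0
    h /= h.max(axis=1, keepdims=True)
    return h


def fold_saf(saf: np.ndarray) -> np.ndarray:
    """Collapse classes j and 2n-j; the central class keeps single weight."""
    saf = np.asarray(saf, dtype=float)
    m = saf.shape[1]
    n_half = (m - 1) // 2
    folded = saf[:, : n_half + 1] + saf[:, ::-1][:, : n_half + 1]
    folded[:, n_half] = saf[:, n_half]
    return folded


def estimate_sfs_em(saf: np.ndarray, folded: bool = False,
                    tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Maximum-likelihood site frequency spectrum by EM.

    Maximizes sum_s log sum_j p_j saf_s(j) over the probability vector p.
    With ``folded`` the SAF is collapsed to minor-allele classes first.
    """
    saf = np.asarray(saf, dtype=float)
    if saf.ndim != 2 or saf.shape[0] < 1:
        raise ValueError("need a (n_sites, 2n+1) SAF matrix with >=1 site")
    if folded:
        saf = fold_saf(saf)
    S, M = saf.shape
    p = np.full(M, 1.0 / M)
    for _ in range(max_iter):
        w = saf * p  # (S, M)
        w /= np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
        p_new = w.mean(axis=0)
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return p


def estimate_2dsfs_em(saf1: np.ndarray, saf2: np.ndarray, folded: bool = False,
                      tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Joint 2D site frequency spectrum by EM.

    Per-site likelihood of class (j, k) is saf1_s(j) * saf2_s(k); the E
    step never materializes the (sites x classes x classes) tensor — the
    update factorizes as p * ((saf1/Z)^T saf2) / S.
    """
    saf1 = np.asarray(saf1, dtype=float)
    saf2 = np.asarray(saf2, dtype=float)
    if saf1.shape[0] != saf2.shape[0]:
        raise CongruenceError(
            f"SAF site counts differ: {saf1.shape[0]} vs {saf2.shape[0]}"
        )
    if folded:
        saf1, saf2 = fold_saf(saf1), fold_saf(saf2)
    S = saf1.shape[0]
    M1, M2 = saf1.shape[1], saf2.shape[1]
    p = np.full((M1, M2), 1.0 / (M1 * M2))
    for _ in range(max_iter):
        z = np.maximum(((saf1 @ p) * saf2).sum(axis=1), 1e-300)
        p_new = p * ((saf1 / z[:, None]).T @ saf2) / S
        p_new /= p_new.sum()
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return p


def _bhatia_components(n1: int, n2: int):
    """Component matrices a(j,k), b(j,k) over all class pairs."""
    p1 = np.arange(2 * n1 + 1) / (2.0 * n1)
    p2 = np.arange(2 * n2 + 1) / (2.0 * n2)
    P1, P2 = np.meshgrid(p1, p2, indexing="ij")
    a = (P1 - P2) ** 2 \
        - P1 * (1 - P1) / (2 * n1 - 1) \
        - P2 * (1 - P2) / (2 * n2 - 1)
    b = P1 * (1 - P2) + P2 * (1 - P1)
    return a, b


def persite_fst(saf1: np.ndarray, saf2: np.ndarray, sfs2d: np.ndarray):
    """Posterior-expected Hudson/Bhatia components per site.

    The posterior over joint classes (j, k) at site s is proportional to
    sfs2d[j,k] * saf1_s(j) * saf2_s(k); a_s and b_s are its expectations of
    the component matrices. Returns ``(a, b)`` arrays over sites. Note b_s
    >= a_s is not guaranteed — the finite-sample correction can push a_s
    below 0 or (rarely) above b_s.
    """
    saf1 = np.atleast_2d(np.asarray(saf1, dtype=float))
    saf2 = np.atleast_2d(np.asarray(saf2, dtype=float))
    if saf1.shape[0] != saf2.shape[0]:
        raise CongruenceError("SAF site counts differ")
    n1 = (saf1.shape[1] - 1) // 2
    n2 = (saf2.shape[1] - 1) // 2
    A, B = _bhatia_components(n1, n2)
    z = np.maximum(((saf1 @ sfs2d) * saf2).sum(axis=1), 1e-300)
    a = ((saf1 @ (sfs2d * A)) * saf2).sum(axis=1) / z
    b = ((saf1 @ (sfs2d * B)) * saf2).sum(axis=1) / z
    return a, b


def global_weighted_fst(a: np.ndarray, b: np.ndarray) -> float:
    """Ratio-of-sums weighted FST over all retained sites."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = b.sum()
    if denom <= 0:
        raise ValueError("weighted FST undefined: sum of b components is 0")
    return float(a.sum() / denom)


def sliding_window_fst(components: pd.DataFrame, win_bp: int = 1000,
                       step_bp: int = 100, chrom_lengths: dict | None = None
                       ) -> pd.DataFrame:
    """Ratio-of-sums FST in sliding windows of ``win_bp`` stepped by
    ``step_bp`` base pairs (1-based inclusive bounds).

    ``components`` needs columns chrom, pos, a, b sorted by (chrom, pos).
    Windows containing no site, or with non-positive summed b, are omitted.
    The per-window ratio is clamped to [-1, 1] for reporting.
    """
    req = {"chrom", "pos", "a", "b"}
    if not req.issubset(components.columns):
        raise CongruenceError(f"components table needs columns {sorted(req)}")
    rows = []
    for chrom, grp in components.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise CongruenceError(f"sites on {chrom} are not sorted by position")
        a = grp["a"].to_numpy()
        b = grp["b"].to_numpy()
        ca = np.concatenate([[0.0], np.cumsum(a)])
        cb = np.concatenate([[0.0], np.cumsum(b)])
        length = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        starts = np.arange(1, length + 1, step_bp)
        ends = starts + win_bp - 1
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n_sites = hi - lo
        sum_a = ca[hi] - ca[lo]
        sum_b = cb[hi] - cb[lo]
        keep = (n_sites > 0) & (sum_b > 0)
        fst = np.clip(sum_a[keep] / sum_b[keep], -1.0, 1.0)
        rows.append(pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts[keep],
                "end": ends[keep],
                "midpoint": (starts[keep] + ends[keep]) / 2.0,
                "n_sites": n_sites[keep],
                "fst": fst,
            }
        ))
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "midpoint", "n_sites", "fst"]
        )
    return pd.concat(rows, ignore_index=True)


def hudson_fst_genotypes(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson/Bhatia weighted FST straight from genotype matrices.

    ``g1``, ``g2`` are (n_sites, n_ind) minor-allele dosages in {0,1,2}.
    This is the high-coverage oracle route: compute sample frequencies,
    plug into the same a/b component formulas, take the ratio of sums.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = g1.shape[1], g2.shape[1]
    p1 = g1.sum(axis=1) / (2.0 * n1)
    p2 = g2.sum(axis=1) / (2.0 * n2)
    a = (p1 - p2) ** 2 \
        - p1 * (1 - p1) / (2 * n1 - 1) \
        - p2 * (1 - p2) / (2 * n2 - 1)
    b = p1 * (1 - p2) + p2 * (1 - p1)
    return global_weighted_fst(a, b)
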