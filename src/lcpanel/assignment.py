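"""K-fold cross-validated population assignment over nested marker panels.

Given a ranked locus list, panels of the top 5, 10, 15, ... loci (plus the
full list if its length is not a multiple of five) are each evaluated by
K-fold cross-validation for every K in 2..10: individuals are randomly
partitioned into K class-stratified folds, each fold is classified once by
a model trained on the others, and the assignment rate is the fraction of
all individuals whose single test prediction is correct (micro-averaged,
so fold-size imbalance cannot bias it). The headline curve is the mean
rate over the nine values of K at each panel size.

The default classifier is the canonical supervised workflow for this kind
of panel validation: center and scale the training dosages, project onto
the top principal components of the training set, and classify test
projections with a linear discriminant. Gaussian naive Bayes on raw
dosages and the package's own random forest are available as alternates.
Fold randomness is derived from (seed, K) so every curve is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "kfold_partition",
    "train_and_classify",
    "evaluate_panels",
    "panel_pca",
    "PanelPCA",
]


def kfold_partition(y, K: int, rng=None) -> np.ndarray:
    """Random class-stratified partition into K folds.

    Returns fold labels 0..K-1, one per individual. Fold sizes differ by
    at most one, both overall and within every class.
    """
    y = np.asarray(y)
    n = len(y)
    if not (2 <= K <= n):
        raise ValueError(f"K must be in [2, {n}]")
    rng = np.random.default_rng(rng)
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        rng.shuffle(rows)
        # continue the fold cycle across classes so overall sizes balance
        labels = (np.arange(len(rows)) + offset) % K
        folds[rows] = labels
        offset += len(rows)
    return folds


def _lda_in_pc_space(Ptr, ytr, Pte):
    classes = np.unique(ytr)
    n, m = Ptr.shape
    means = np.stack([Ptr[ytr == c].mean(axis=0) for c in classes])
    centered = Ptr - means[np.searchsorted(classes, ytr)]
    pooled = centered.T @ centered / max(n - len(classes), 1)
    pooled += 1e-8 * np.eye(m)
    inv = np.linalg.inv(pooled)
    # linear discriminant scores with equal priors
    scores = Pte @ inv @ means.T - 0.5 * np.einsum("ci,ij,cj->c", means, inv, means)
    return classes[np.argmax(scores, axis=1)]


def _pca_lda_fit_predict(Xtr, ytr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Ztr = (Xtr - mu) / sd
    Zte = (Xte - mu) / sd
    n, p = Ztr.shape
    m = max(1, min(p, n - 2, 10))
    _, _, vt = np.linalg.svd(Ztr, full_matrices=False)
    comps = vt[:m]
    return _lda_in_pc_space(Ztr @ comps.T, ytr, Zte @ comps.T)


def _naive_bayes_fit_predict(Xtr, ytr, Xte):
    classes = np.unique(ytr)
    log_post = np.zeros((len(Xte), len(classes)))
    for ci, c in enumerate(classes):
        block = Xtr[ytr == c]
        mu = block.mean(axis=0)
        var = block.var(axis=0) + 1e-6
        log_post[:, ci] = (
            -0.5 * (((Xte - mu) ** 2) / var + np.log(2 * np.pi * var)).sum(axis=1)
        )
    return classes[np.argmax(log_post, axis=1)]


def train_and_classify(Xtr, ytr, Xte, model: str = "pca_lda", rng=None):
    """Train on (Xtr, ytr), label Xte. Models: pca_lda (default),
    naive_bayes, rf."""
    Xtr = np.asarray(Xtr, dtype=float)
    Xte = np.atleast_2d(np.asarray(Xte, dtype=float))
    ytr = np.asarray(ytr)
    classes, counts = np.unique(ytr, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >=2 training individuals in each of >=2 classes")
    if model == "pca_lda":
        return _pca_lda_fit_predict(Xtr, ytr, Xte)
    if model == "naive_bayes":
        return _naive_bayes_fit_predict(Xtr, ytr, Xte)
    if model == "rf":
        from .selection import fit_random_forest

        forest = fit_random_forest(
            Xtr.astype(np.int8), ytr, n_trees=200,
            rng=np.random.default_rng(rng),
        )
        return forest.predict(Xte.astype(np.int8))
    raise ValueError(f"unknown model {model!r}")


def panel_size_sequence(total: int, step: int = 5) -> list:
    """5, 10, ... up to ``total``, ending with ``total`` itself."""
    if total < step:
        return [total]
    sizes = list(range(step, total + 1, step))
    if sizes[-1] != total:
        sizes.append(total)
    return sizes


@dataclass
class PanelEvaluation:
    rates: pd.DataFrame   # panel_size, K, rate
    curve: pd.DataFrame   # panel_size, mean_rate (mean over K)
    best_size: int
    best_rate: float


def evaluate_panels(ranked_loci, X, y, step: int = 5,
                    k_range=range(2, 11), seed: int = 0,
                    model: str = "pca_lda") -> PanelEvaluation:
    """Assignment-rate curve over nested panel sizes.

    ``ranked_loci`` are column indices of ``X`` in rank order; ``X`` must
    be fully imputed. For each panel size and each K, the rate is the
    fraction of individuals correctly assigned in their single test
    appearance; the curve averages over K. Fold partitions are seeded from
    (seed, K) so each K reuses the same folds across panel sizes.
    """
    ranked_loci = np.asarray(list(ranked_loci), dtype=int)
    X = np.asarray(X)
    y = np.asarray(y)
    sizes = panel_size_sequence(len(ranked_loci), step)
    k_range = list(k_range)
    fold_sets = {
        K: kfold_partition(y, K, rng=np.random.default_rng([seed, K]))
        for K in k_range
    }
    if model == "pca_lda":
        rates = _evaluate_panels_pca_lda(ranked_loci, X, y, sizes, fold_sets)
    else:
        records = []
        for size in sizes:
            Xp = X[:, ranked_loci[:size]]
            for K in k_range:
                folds = fold_sets[K]
                pred = np.empty(len(y), dtype=y.dtype)
                for k in range(K):
                    test = folds == k
                    pred[test] = train_and_classify(
                        Xp[~test], y[~test], Xp[test], model=model,
                        rng=np.random.default_rng([seed, K, k]),
                    )
                records.append(
                    {"panel_size": size, "K": K, "rate": float((pred == y).mean())}
                )
        rates = pd.DataFrame(records)
    curve = (
        rates.groupby("panel_size", as_index=False)["rate"]
        .mean()
        .rename(columns={"rate": "mean_rate"})
    )
    best_idx = curve["mean_rate"].idxmax()
    return PanelEvaluation(
        rates=rates,
        curve=curve,
        best_size=int(curve.loc[best_idx, "panel_size"]),
        best_rate=float(curve.loc[best_idx, "mean_rate"]),
    )


def _evaluate_panels_pca_lda(ranked_loci, X, y, sizes, fold_sets):
    """Nested-panel PCA+LDA evaluation via incremental Gram matrices.

    Because panels are nested prefixes of the ranked list, the train-train
    Gram matrix of standardized dosages (and the test-train cross Gram)
    grow by one rank-``step`` update per panel size; the top principal
    components then come from an n x n eigendecomposition instead of a
    fresh SVD of the full feature block. Identical model to
    :func:`_pca_lda_fit_predict`, just computed incrementally.
    """
    Xf = X[:, ranked_loci].astype(float)
    n = len(y)
    records = []
    for K, folds in fold_sets.items():
        correct = {size: 0 for size in sizes}
        for k in range(K):
            te = folds == k
            tr = ~te
            n_tr = int(tr.sum())
            mu = Xf[tr].mean(axis=0)
            sd = Xf[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Ztr = (Xf[tr] - mu) / sd
            Zte = (Xf[te] - mu) / sd
            G = np.zeros((n_tr, n_tr))
            C = np.zeros((int(te.sum()), n_tr))
            prev = 0
            for size in sizes:
                B_tr = Ztr[:, prev:size]
                B_te = Zte[:, prev:size]
                G += B_tr @ B_tr.T
                C += B_te @ B_tr.T
                prev = size
                m = max(1, min(size, n_tr - 2, 10))
                lam, U = np.linalg.eigh(G)
                lam = np.maximum(lam[::-1][:m], 1e-10)
                U = U[:, ::-1][:, :m]
                Ptr = U * np.sqrt(lam)
                Pte = C @ (U / np.sqrt(lam))
                pred = _lda_in_pc_space(Ptr, y[tr], Pte)
                correct[size] += int((pred == y[te]).sum())
        for size in sizes:
            records.append(
                {"panel_size": size, "K": K, "rate": correct[size] / n}
            )
    return pd.DataFrame(records).sort_values(
        ["panel_size", "K"], ignore_index=True
    )


@dataclass
class PanelPCA:
    scores: np.ndarray            # (N, 2) PC scores
    variance_explained: np.ndarray
    ellipses: dict                # group -> (mean (2,), cov (2, 2))


def panel_pca(gl, maf, groups, k: int = 2) -> PanelPCA:
    """PCA restricted to a marker panel, with per-group normal ellipses.

    ``gl`` is a GenotypeLikelihoodMatrix already subset to the panel loci;
    ``groups`` labels each individual. Returns the first two PC scores,
    the variance fraction of every PC, and each group's score mean and
    covariance (the 95% normal ellipse is mean + 2.448-sigma contour of
    that covariance).
    """
    from .structure import gl_covariance

    if gl.n_sites < 2:
        raise ValueError("panel must contain at least 2 loci")
    cov = gl_covariance(gl, maf, k=k)
    scores = cov.pc_scores[:, :2]
    groups = np.asarray(groups)
    ellipses = {}
    for g in np.unique(groups):
        pts = scores[groups == g]
        ellipses[g] = (pts.mean(axis=0), np.cov(pts.T))
    return PanelPCA(scores, cov.variance_explained, ellipses)
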