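"""Informative-locus selection: guided regularized random forest and
ranked FST, with random-forest proximity imputation of missing genotypes.

Two complementary selectors operate on hard-called genotype dosages:

* ``rank_fst_select`` simply ranks loci by their per-site FST ratio
  a_s / b_s, highest first — the classical single-locus view.
* ``grrf_select`` runs a preliminary random forest to obtain importance
  scores, normalizes them to per-locus penalties
  lambda_j = (1 - gamma) + gamma * imp_j / max(imp), and then grows
  regularized forests in which a not-yet-used locus must beat the penalty
  to enter (gamma = 0 recovers plain RF; larger gamma prunes harder).
  Selection is repeated over several independently seeded runs; any locus
  with positive out-of-bag permutation importance in any run is selected,
  and the final ranking is by mean importance across runs (ties broken by
  locus id).

Only loci with a positive per-site FST ratio are offered to the GRRF by
the pipeline; missing genotypes are imputed beforehand with
``rf_impute``: initialize missing entries at the within-class mode, then
iterate fit-forest / proximity-weighted averaging, where the proximity of
two individuals is the fraction of trees in which they share a leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _forest

__all__ = [
    "RandomForest",
    "fit_random_forest",
    "grrf_select",
    "rank_fst_select",
    "rf_impute",
]

_MAX_SEED = 2 ** 31 - 1


def _check_xy(X, y):
    X = np.ascontiguousarray(X, dtype=np.int8)
    if X.min() < 0 or X.max() > 2:
        raise ValueError("genotype features must be dosages in {0, 1, 2}")
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes in y")
    return X, classes, np.ascontiguousarray(y_codes, dtype=np.int8)


@dataclass
class RandomForest:
    """A fitted forest; thin handle over the tree arrays."""

    feature: np.ndarray
    thresh: np.ndarray
    left: np.ndarray
    right: np.ndarray
    pred: np.ndarray
    n_nodes: np.ndarray
    classes: np.ndarray
    importance: np.ndarray   # OOB permutation mean decrease accuracy
    oob_error: float
    used_features: np.ndarray

    @property
    def n_trees(self) -> int:
        return self.feature.shape[0]

    def predict(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.int8)
        votes = _forest._predict_votes(
            self.feature, self.thresh, self.left, self.right, self.pred,
            X, len(self.classes)
        )
        return self.classes[votes.argmax(axis=1)]

    def proximity(self, X) -> np.ndarray:
        """Fraction of trees in which each pair of rows shares a leaf."""
        X = np.ascontiguousarray(X, dtype=np.int8)
        leaves = _forest._leaf_indices(
            self.feature, self.thresh, self.left, self.right, X
        )
        return _forest._proximity(leaves, self.n_trees)


def fit_random_forest(X, y, n_trees: int = 500, mtry: int | None = None,
                      rng=None, penalties: np.ndarray | None = None
                      ) -> RandomForest:
    """Fit a classification forest and compute OOB permutation importance.

    ``penalties`` (per-feature gain multipliers for not-yet-used features)
    switches on regularized growth — used internally by :func:`grrf_select`.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(rng)
    X, classes, y_codes = _check_xy(X, y)
    n, p = X.shape
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    mtry = min(mtry, p)
    regularize = penalties is not None
    lam = (np.ones(p) if penalties is None
           else np.ascontiguousarray(penalties, dtype=np.float64))
    boots = rng.integers(0, n, size=(n_trees, n)).astype(np.int64)
    seeds = rng.integers(0, _MAX_SEED, size=2 * n_trees).astype(np.int64)
    feature, thresh, left, right, pred, n_nodes, used = _forest._fit_forest(
        X, y_codes, len(classes), boots, mtry, lam, regularize,
        seeds[:n_trees]
    )
    inbag = np.zeros((n_trees, n), dtype=np.int16)
    for t in range(n_trees):
        np.add.at(inbag[t], boots[t], 1)
    mda, oob_err = _forest._oob_importance(
        feature, thresh, left, right, pred, n_nodes,
        X.copy(), y_codes, inbag, seeds[n_trees:]
    )
    return RandomForest(feature, thresh, left, right, pred, n_nodes,
                        classes, mda, float(oob_err), used)


def grrf_select(X, y, locus_ids, n_runs: int = 10, n_trees: int = 5000,
                gamma: float = 0.3, rng=None, mtry: int | None = None,
                preliminary: RandomForest | None = None) -> pd.DataFrame:
    """Guided regularized random forest selection over repeated runs.

    One preliminary plain forest guides all runs (pass ``preliminary`` to
    reuse an existing fit). Returns the importance table: per locus the
    per-run importances, how many runs selected it (positive importance),
    the mean importance across runs, the selected flag and the final rank
    (mean importance descending, ties by locus id ascending).
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must be in [0, 1]")
    rng = np.random.default_rng(rng)
    locus_ids = list(locus_ids)
    p = np.asarray(X).shape[1]
    if len(locus_ids) != p:
        raise ValueError("locus_ids length must match feature count")
    if preliminary is None:
        preliminary = fit_random_forest(X, y, n_trees=n_trees, mtry=mtry,
                                        rng=rng)
    imp = np.maximum(preliminary.importance, 0.0)
    top = imp.max()
    imp_norm = imp / top if top > 0 else np.zeros_like(imp)
    penalties = (1.0 - gamma) + gamma * imp_norm

    run_imps = np.empty((n_runs, p))
    for r in range(n_runs):
        forest = fit_random_forest(X, y, n_trees=n_trees, mtry=mtry,
                                   rng=rng, penalties=penalties)
        run_imps[r] = forest.importance

    selected = (run_imps > 0).any(axis=0)
    table = pd.DataFrame({"locus": locus_ids})
    for r in range(n_runs):
        table[f"mda_run{r + 1}"] = run_imps[r]
    table["n_runs_positive"] = (run_imps > 0).sum(axis=0)
    table["mean_mda"] = run_imps.mean(axis=0)
    table["selected"] = selected
    order = table.sort_values(
        ["mean_mda", "locus"], ascending=[False, True], kind="stable"
    ).index
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table["rank"] = rank
    return table.sort_values("rank").reset_index(drop=True)


def rank_fst_select(components: pd.DataFrame, n_select: int | None = None
                    ) -> pd.DataFrame:
    """Rank loci by per-site FST ratio a/b, highest first.

    ``components`` needs columns chrom, pos, a, b. Ties are broken by
    (chrom, pos) ascending. ``n_select`` beyond the number of loci
    truncates with a warning.
    """
    df = components.copy()
    b = df["b"].to_numpy(dtype=float)
    df["fst_ratio"] = np.where(b > 0, df["a"].to_numpy(dtype=float) / b, -np.inf)
    df = df.sort_values(
        ["fst_ratio", "chrom", "pos"], ascending=[False, True, True],
        kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if n_select is not None:
        if n_select > len(df):
            import warnings

            warnings.warn(
                f"requested {n_select} loci but only {len(df)} available"
            )
            n_select = len(df)
        df = df.head(n_select)
    return df


def rf_impute(X, y, missing=None, n_iter: int = 10, n_trees: int = 2000,
              rng=None, mtry: int | None = None) -> np.ndarray:
    """Random-forest proximity imputation of missing genotype dosages.

    Missing entries start at the within-class per-locus mode, then each
    iteration refits a forest on the completed matrix and replaces every
    missing entry with the proximity-weighted average of the observed
    entries in its column, rounded back to {0, 1, 2}. Observed entries are
    never modified; a matrix with no missing entries is returned unchanged.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X)
    if missing is None:
        missing = X < 0
    missing = np.asarray(missing, dtype=bool)
    if not missing.any():
        return X.astype(np.int8, copy=True)
    if missing.all(axis=0).any():
        bad = int(np.flatnonzero(missing.all(axis=0))[0])
        raise ValueError(f"locus column {bad} is entirely missing")
    y = np.asarray(y)
    Xc = X.astype(np.int8, copy=True)
    # within-class mode start
    for cls in np.unique(y):
        rows = y == cls
        block = Xc[rows]
        bmiss = missing[rows]
        for j in range(Xc.shape[1]):
            col_missing = bmiss[:, j]
            if not col_missing.any():
                continue
            obs = block[~col_missing, j]
            if len(obs) == 0:  # class has no data here: global mode
                obs = Xc[~missing[:, j], j]
            mode = np.bincount(obs, minlength=3).argmax()
            block[col_missing, j] = mode
        Xc[rows] = block
    obs_mask = ~missing
    for _ in range(n_iter):
        forest = fit_random_forest(Xc, y, n_trees=n_trees, mtry=mtry, rng=rng)
        prox = forest.proximity(Xc)
        np.fill_diagonal(prox, 0.0)
        for j in range(Xc.shape[1]):
            miss_rows = np.flatnonzero(missing[:, j])
            if len(miss_rows) == 0:
                continue
            obs_rows = np.flatnonzero(obs_mask[:, j])
            w = prox[np.ix_(miss_rows, obs_rows)]
            wsum = w.sum(axis=1)
            vals = X[obs_rows, j].astype(float)
            est = np.where(wsum > 0, w @ vals / np.maximum(wsum, 1e-300),
                           vals.mean())
            Xc[miss_rows, j] = np.clip(np.rint(est), 0, 2).astype(np.int8)
    return Xc
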