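"""Numba kernels for the classification random forest.

Features are genotype dosages in {0, 1, 2}, so every feature has at most
two candidate split points (<=0 and <=1); trees are CART with Gini
impurity, grown to purity (minimum node size 1) on bootstrap samples, with
majority-vote leaves.

Regularized growth (the guided/regularized variant): a feature that has
not yet been used anywhere in the forest built so far has its split gain
multiplied by a per-feature penalty lambda_j in (0, 1]; features already
in the forest's feature set compete at full gain. The used-feature set is
forest-level and incremental, which is what produces compact feature sets.

Importance is out-of-bag permutation mean decrease accuracy: per tree, the
accuracy drop on that tree's OOB rows when one feature's OOB values are
permuted, averaged over trees with non-empty OOB; features unused by a
tree contribute a zero drop for that tree.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LEAF = -1


@njit(cache=False)
def _build_tree(X, y, n_classes, boot, mtry, lam, used, regularize,
                feature, thresh, left, right, pred, perm, seed):
    """Grow one tree on bootstrap row indices ``boot``; returns node count.

    Node arrays are preallocated by the caller; ``perm`` is a length-p
    feature permutation scratch buffer; ``used`` is the forest-level
    used-feature set, updated in place as splits are made.
    """
    np.random.seed(seed)
    n = boot.shape[0]
    p = X.shape[1]
    idx = boot.copy()
    # stack of (node, start, end)
    stack_node = np.empty(2 * n + 2, dtype=np.int32)
    stack_lo = np.empty(2 * n + 2, dtype=np.int32)
    stack_hi = np.empty(2 * n + 2, dtype=np.int32)
    n_nodes = 1
    top = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    counts = np.empty(n_classes, dtype=np.int64)
    cnt = np.empty((n_classes, 3), dtype=np.int64)
    while top >= 0:
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        top -= 1
        n_node = hi - lo
        counts[:] = 0
        for i in range(lo, hi):
            counts[y[idx[i]]] += 1
        best_c = 0
        for c in range(1, n_classes):
            if counts[c] > counts[best_c]:
                best_c = c
        pure = counts[best_c] == n_node
        if pure or n_node < 2:
            feature[node] = _LEAF
            pred[node] = best_c
            continue
        parent_score = 0.0
        for c in range(n_classes):
            parent_score += counts[c] * counts[c]
        parent_score /= n_node
        best_gain = 0.0
        best_f = -1
        best_t = -1
        for j in range(mtry):
            r = j + np.random.randint(p - j)
            tmp = perm[j]
            perm[j] = perm[r]
            perm[r] = tmp
            f = perm[j]
            cnt[:, :] = 0
            for i in range(lo, hi):
                cnt[y[idx[i]], X[idx[i], f]] += 1
            for t in range(2):
                nl = 0
                sl = 0.0
                sr = 0.0
                for c in range(n_classes):
                    lcount = cnt[c, 0]
                    if t == 1:
                        lcount += cnt[c, 1]
                    rcount = counts[c] - lcount
                    nl += lcount
                    sl += lcount * lcount
                    sr += rcount * rcount
                nr = n_node - nl
                if nl == 0 or nr == 0:
                    continue
                gain = sl / nl + sr / nr - parent_score
                if gain <= 1e-12:
                    continue
                if regularize and not used[f]:
                    gain *= lam[f]
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_t = t
        if best_f < 0:
            feature[node] = _LEAF
            pred[node] = best_c
            continue
        used[best_f] = True
        # stable partition: rows with X <= t go left
        mid = lo
        buf = np.empty(n_node, dtype=np.int64)
        nb = 0
        for i in range(lo, hi):
            if X[idx[i], best_f] <= best_t:
                idx[mid] = idx[i]
                mid += 1
            else:
                buf[nb] = idx[i]
                nb += 1
        for i in range(nb):
            idx[mid + i] = buf[i]
        feature[node] = best_f
        thresh[node] = best_t
        left[node] = n_nodes
        right[node] = n_nodes + 1
        top += 1
        stack_node[top] = n_nodes
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1
        stack_node[top] = n_nodes + 1
        stack_lo[top] = mid
        stack_hi[top] = hi
        n_nodes += 2
    return n_nodes


@njit(cache=False)
def _fit_forest(X, y, n_classes, boots, mtry, lam, regularize, seeds):
    n_trees = boots.shape[0]
    n = X.shape[0]
    p = X.shape[1]
    max_nodes = 2 * boots.shape[1] + 1
    feature = np.full((n_trees, max_nodes), _LEAF, dtype=np.int32)
    thresh = np.zeros((n_trees, max_nodes), dtype=np.int8)
    left = np.zeros((n_trees, max_nodes), dtype=np.int32)
    right = np.zeros((n_trees, max_nodes), dtype=np.int32)
    pred = np.zeros((n_trees, max_nodes), dtype=np.int8)
    n_nodes = np.zeros(n_trees, dtype=np.int32)
    used = np.zeros(p, dtype=np.bool_)
    perm = np.arange(p).astype(np.int64)
    for t in range(n_trees):
        n_nodes[t] = _build_tree(
            X, y, n_classes, boots[t], mtry, lam, used, regularize,
            feature[t], thresh[t], left[t], right[t], pred[t], perm, seeds[t]
        )
    return feature, thresh, left, right, pred, n_nodes, used


@njit(cache=False)
def _predict_row_tree(feature, thresh, left, right, pred, x):
    node = 0
    while feature[node] != _LEAF:
        if x[feature[node]] <= thresh[node]:
            node = left[node]
        else:
            node = right[node]
    return pred[node]


@njit(cache=False)
def _leaf_row_tree(feature, thresh, left, right, x):
    node = 0
    while feature[node] != _LEAF:
        if x[feature[node]] <= thresh[node]:
            node = left[node]
        else:
            node = right[node]
    return node


@njit(cache=False)
def _predict_votes(feature, thresh, left, right, pred, X, n_classes):
    n_trees = feature.shape[0]
    n = X.shape[0]
    votes = np.zeros((n, n_classes), dtype=np.int64)
    for t in range(n_trees):
        for i in range(n):
            c = _predict_row_tree(feature[t], thresh[t], left[t], right[t],
                                  pred[t], X[i])
            votes[i, c] += 1
    return votes


@njit(cache=False)
def _leaf_indices(feature, thresh, left, right, X):
    n_trees = feature.shape[0]
    n = X.shape[0]
    leaves = np.empty((n_trees, n), dtype=np.int32)
    for t in range(n_trees):
        for i in range(n):
            leaves[t, i] = _leaf_row_tree(feature[t], thresh[t], left[t],
                                          right[t], X[i])
    return leaves


@njit(cache=False)
def _proximity(leaves, n_trees):
    n = leaves.shape[1]
    prox = np.zeros((n, n), dtype=np.float64)
    for t in range(leaves.shape[0]):
        for i in range(n):
            li = leaves[t, i]
            for j in range(i + 1, n):
                if leaves[t, j] == li:
                    prox[i, j] += 1.0
    for i in range(n):
        for j in range(i + 1, n):
            prox[j, i] = prox[i, j]
        prox[i, i] = n_trees
    return prox / n_trees


@njit(cache=False)
def _oob_importance(feature, thresh, left, right, pred, n_nodes,
                    X, y, inbag, seeds):
    """Mean decrease accuracy per feature across trees."""
    n_trees = feature.shape[0]
    n, p = X.shape
    mda = np.zeros(p, dtype=np.float64)
    oob_correct = 0.0
    oob_total = 0.0
    trees_with_oob = 0
    tree_used = np.zeros(p, dtype=np.bool_)
    for t in range(n_trees):
        n_oob = 0
        for i in range(n):
            if inbag[t, i] == 0:
                n_oob += 1
        if n_oob == 0:
            continue
        trees_with_oob += 1
        oob_rows = np.empty(n_oob, dtype=np.int64)
        k = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob_rows[k] = i
                k += 1
        correct = 0
        for i in range(n_oob):
            r = oob_rows[i]
            if _predict_row_tree(feature[t], thresh[t], left[t], right[t],
                                 pred[t], X[r]) == y[r]:
                correct += 1
        oob_correct += correct
        oob_total += n_oob
        acc = correct / n_oob
        tree_used[:] = False
        for node in range(n_nodes[t]):
            if feature[t, node] != _LEAF:
                tree_used[feature[t, node]] = True
        np.random.seed(seeds[t])
        col = np.empty(n_oob, dtype=X.dtype)
        for f in range(p):
            if not tree_used[f]:
                continue
            for i in range(n_oob):
                col[i] = X[oob_rows[i], f]
            # Fisher-Yates permutation of the OOB column
            for i in range(n_oob - 1, 0, -1):
                j = np.random.randint(i + 1)
                tmp = col[i]
                col[i] = col[j]
                col[j] = tmp
            correct_perm = 0
            for i in range(n_oob):
                r = oob_rows[i]
                saved = X[r, f]
                X[r, f] = col[i]
                if _predict_row_tree(feature[t], thresh[t], left[t], right[t],
                                     pred[t], X[r]) == y[r]:
                    correct_perm += 1
                X[r, f] = saved
            mda[f] += acc - correct_perm / n_oob
    if trees_with_oob > 0:
        mda /= trees_with_oob
    oob_err = 1.0 - (oob_correct / oob_total if oob_total > 0 else 0.0)
    return mda, oob_err
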