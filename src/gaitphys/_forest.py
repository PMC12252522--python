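"""Compiled random-forest backend for the subject-level scoring protocol.

A Breiman random forest for binary classification with the same algorithm
as scikit-learn's defaults — bootstrap resampling, unlimited-depth CART
trees with Gini impurity, sqrt(d) feature subsampling, midpoint
thresholds, probability-averaged voting, and normalised mean-decrease-in-
impurity feature importances — compiled with numba so that the
leave-one-out protocol (thousands of 500-tree fits) runs at interactive
speed on one core.  Statistical agreement with
``sklearn.ensemble.RandomForestClassifier`` is asserted in the test
suite, and the scorer can be switched to the scikit-learn backend.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["FastRandomForest"]


@njit(cache=True, inline="always")
def _insertion_sort_pairs(vals, labs, lo, hi):
    for i in range(lo + 1, hi):
        v = vals[i]
        l = labs[i]
        j = i - 1
        while j >= lo and vals[j] > v:
            vals[j + 1] = vals[j]
            labs[j + 1] = labs[j]
            j -= 1
        vals[j + 1] = v
        labs[j + 1] = l


@njit(cache=True)
def _qsort_pairs(vals, labs, lo0, hi0, stack):
    top = 0
    stack[0, 0] = lo0
    stack[0, 1] = hi0
    while top >= 0:
        lo = stack[top, 0]
        hi = stack[top, 1]
        top -= 1
        while hi - lo > 20:
            mid = (lo + hi) // 2
            if vals[mid] < vals[lo]:
                vals[mid], vals[lo] = vals[lo], vals[mid]
                labs[mid], labs[lo] = labs[lo], labs[mid]
            if vals[hi - 1] < vals[lo]:
                vals[hi - 1], vals[lo] = vals[lo], vals[hi - 1]
                labs[hi - 1], labs[lo] = labs[lo], labs[hi - 1]
            if vals[hi - 1] < vals[mid]:
                vals[hi - 1], vals[mid] = vals[mid], vals[hi - 1]
                labs[hi - 1], labs[mid] = labs[mid], labs[hi - 1]
            p = vals[mid]
            i = lo
            j = hi - 1
            while True:
                while vals[i] < p:
                    i += 1
                while vals[j] > p:
                    j -= 1
                if i >= j:
                    break
                vals[i], vals[j] = vals[j], vals[i]
                labs[i], labs[j] = labs[j], labs[i]
                i += 1
                j -= 1
            top += 1
            stack[top, 0] = j + 1
            stack[top, 1] = hi
            hi = j + 1
        _insertion_sort_pairs(vals, labs, lo, hi)


@njit(cache=True)
def _build_tree(XT, y, max_features, feat_buf, vbuf, lbuf, qstack, nodes,
                stack, boot, importances, seed):
    """Grow one CART tree on a bootstrap sample; fill the node table.

    Node layout: (feature, threshold, left, right, n_class0, n_class1);
    feature == -1 marks a leaf.  Accumulates unnormalised mean-decrease-
    in-impurity into ``importances``.
    """
    np.random.seed(seed)
    m = XT.shape[1]
    d = XT.shape[0]
    for i in range(m):
        boot[i] = np.random.randint(0, m)
    top = 0
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = m
    n_nodes = 1
    while top >= 0:
        node = stack[top, 0]
        s = stack[top, 1]
        e = stack[top, 2]
        top -= 1
        c1 = 0
        for i in range(s, e):
            c1 += y[boot[i]]
        c0 = (e - s) - c1
        nodes[node, 4] = c0
        nodes[node, 5] = c1
        if c0 == 0 or c1 == 0 or e - s < 2:
            nodes[node, 0] = -1.0
            continue
        for j in range(d):
            feat_buf[j] = j
        best_gain = -1.0
        best_f = -1
        best_thr = 0.0
        ntot = float(e - s)
        parent_gini = 1.0 - ((c0 / ntot) ** 2 + (c1 / ntot) ** 2)
        nn = e - s
        for kf in range(max_features):
            r = kf + np.random.randint(0, d - kf)
            f = feat_buf[r]
            feat_buf[r] = feat_buf[kf]
            feat_buf[kf] = f
            for i in range(nn):
                b = boot[s + i]
                vbuf[i] = XT[f, b]
                lbuf[i] = y[b]
            _qsort_pairs(vbuf, lbuf, 0, nn, qstack)
            l1 = 0
            for i in range(nn - 1):
                l1 += lbuf[i]
                v = vbuf[i]
                if vbuf[i + 1] <= v:
                    continue
                nl = i + 1
                nr = nn - nl
                l0 = nl - l1
                r1 = c1 - l1
                r0 = c0 - l0
                gl = 1.0 - ((l0 / nl) ** 2 + (l1 / nl) ** 2)
                gr = 1.0 - ((r0 / nr) ** 2 + (r1 / nr) ** 2)
                gain = parent_gini - (nl * gl + nr * gr) / ntot
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (v + vbuf[i + 1])
        if best_f < 0 or best_gain <= 1e-12:
            nodes[node, 0] = -1.0
            continue
        i = s
        j = e - 1
        while i <= j:
            if XT[best_f, boot[i]] <= best_thr:
                i += 1
            else:
                tmp = boot[i]
                boot[i] = boot[j]
                boot[j] = tmp
                j -= 1
        mid = i
        if mid == s or mid == e:
            nodes[node, 0] = -1.0
            continue
        importances[best_f] += ntot / m * best_gain
        left = n_nodes
        right = n_nodes + 1
        n_nodes += 2
        nodes[node, 0] = best_f
        nodes[node, 1] = best_thr
        nodes[node, 2] = left
        nodes[node, 3] = right
        top += 1
        stack[top, 0] = left
        stack[top, 1] = s
        stack[top, 2] = mid
        top += 1
        stack[top, 0] = right
        stack[top, 1] = mid
        stack[top, 2] = e
    return n_nodes


@njit(cache=True)
def _fit_forest(XT, y, n_trees, max_features, seeds):
    d, n = XT.shape
    max_nodes = 4 * n + 10
    all_nodes = np.zeros((n_trees, max_nodes, 6))
    importances = np.zeros(d)
    tree_imp = np.empty(d)
    feat_buf = np.empty(d, np.int64)
    vbuf = np.empty(n, np.float32)
    lbuf = np.empty(n, np.int64)
    qstack = np.empty((64, 2), np.int64)
    stack = np.empty((2 * n + 10, 3), np.int64)
    boot = np.empty(n, np.int64)
    for t in range(n_trees):
        tree_imp[:] = 0.0
        _build_tree(XT, y, max_features, feat_buf, vbuf, lbuf, qstack,
                    all_nodes[t], stack, boot, tree_imp, seeds[t])
        tot = tree_imp.sum()
        if tot > 0:
            importances += tree_imp / tot
    return all_nodes, importances / n_trees


@njit(cache=True)
def _predict_proba(all_nodes, X):
    n_trees = all_nodes.shape[0]
    n = X.shape[0]
    out = np.zeros((n, 2))
    for t in range(n_trees):
        nodes = all_nodes[t]
        for i in range(n):
            node = 0
            while nodes[node, 0] >= 0:
                if X[i, int(nodes[node, 0])] <= nodes[node, 1]:
                    node = int(nodes[node, 2])
                else:
                    node = int(nodes[node, 3])
            tot = nodes[node, 4] + nodes[node, 5]
            out[i, 0] += nodes[node, 4] / tot
            out[i, 1] += nodes[node, 5] / tot
    return out / n_trees


class FastRandomForest:
    """Minimal sklearn-like interface around the compiled forest.

    Binary labels must be 0/1.  ``max_features=None`` means sqrt(d),
    mirroring the scikit-learn classifier default.
    """

    def __init__(self, n_estimators: int = 500, max_features: int | None = None,
                 random_state: int | np.random.Generator = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n, d) with matching y")
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("labels must be 0/1")
        d = X.shape[1]
        k = self.max_features or max(1, int(np.sqrt(d)))
        rng = (self.random_state
               if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        seeds = rng.integers(0, 2**31 - 1, size=self.n_estimators).astype(np.int64)
        XT = np.ascontiguousarray(X.T)
        self._nodes, self.feature_importances_ = _fit_forest(
            XT, y, self.n_estimators, k, seeds
        )
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32)
        return _predict_proba(self._nodes, X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(np.int64)
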