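"""Exact path-dependent SHAP values for sklearn decision-tree ensembles.

Implements the polynomial-time tree-traversal algorithm (Lundberg et al.'s
TreeSHAP): a single depth-first pass per tree maintains the set of unique
features on the current decision path together with, for each, the fraction
of "zero" (cover-weighted) and "one" (instance-following) paths that flow
through, and the Shapley-kernel subset weights.  Conditional expectations
for feature subsets follow the tree's own cover proportions, so the values
sum exactly to ``f(x) - E[f]`` with E taken over the training cover.

The companion brute-force oracle (subset enumeration over the features used
by the tree) lives in the test suite; this module is validated against it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values"]


def _extend(d, z, o, w, pz, po, pi):
    l = len(d)
    d = d + [pi]
    z = z + [pz]
    o = o + [po]
    w = w + [1.0 if l == 0 else 0.0]
    for i in range(l - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / (l + 1)
        w[i] = pz * w[i] * (l - i) / (l + 1)
    return d, z, o, w


def _unwind(d, z, o, w, i):
    l = len(d) - 1
    n = w[l]
    d, z, o, w = list(d), list(z), list(o), list(w)
    oi, zi = o[i], z[i]
    for j in range(l - 1, -1, -1):
        if oi != 0:
            t = w[j]
            w[j] = n * (l + 1) / ((j + 1) * oi)
            n = t - w[j] * zi * (l - j) / (l + 1)
        else:
            w[j] = w[j] * (l + 1) / (zi * (l - j))
    for j in range(i, l):
        d[j], z[j], o[j] = d[j + 1], z[j + 1], o[j + 1]
    return d[:-1], z[:-1], o[:-1], w[:-1]


def _unwound_sum(d, z, o, w, i):
    l = len(d) - 1
    oi, zi = o[i], z[i]
    total = 0.0
    if oi != 0:
        n = w[l]
        for j in range(l - 1, -1, -1):
            t = n / ((j + 1) * oi)
            total += t
            n = w[j] - t * zi * (l - j)
    else:
        for j in range(l - 1, -1, -1):
            total += w[j] / (zi * (l - j))
    return total * (l + 1)


def tree_shap_values(tree, x: np.ndarray) -> np.ndarray:
    """SHAP values of one fitted ``sklearn.tree._tree.Tree`` at instance x."""
    left = tree.children_left
    right = tree.children_right
    feature = tree.feature
    threshold = tree.threshold
    values = tree.value[:, 0, 0]
    cover = tree.weighted_n_node_samples
    phi = np.zeros(x.shape[0])

    def recurse(j, d, z, o, w, pz, po, pi):
        d, z, o, w = _extend(d, z, o, w, pz, po, pi)
        if left[j] < 0:  # leaf
            for i in range(1, len(d)):
                phi[d[i]] += _unwound_sum(d, z, o, w, i) * (o[i] - z[i]) * values[j]
            return
        f = feature[j]
        hot, cold = (left[j], right[j]) if x[f] <= threshold[j] else (right[j], left[j])
        iz = io = 1.0
        k = None
        for q in range(1, len(d)):
            if d[q] == f:
                k = q
                break
        if k is not None:
            iz, io = z[k], o[k]
            d, z, o, w = _unwind(d, z, o, w, k)
        recurse(hot, d, z, o, w, iz * cover[hot] / cover[j], io, f)
        recurse(cold, d, z, o, w, iz * cover[cold] / cover[j], 0.0, f)

    recurse(0, [], [], [], [], 1.0, 1.0, -1)
    return phi


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """SHAP values and base value for a fitted RandomForestRegressor.

    Returns (phi, base) with phi of shape (n_instances, n_features); the
    forest prediction equals ``base + phi.sum(axis=1)`` row by row.
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros_like(X)
    base = 0.0
    for est in forest.estimators_:
        t = est.tree_
        base += t.value[0, 0, 0]
        for r in range(X.shape[0]):
            phi[r] += tree_shap_values(t, X[r])
    k = len(forest.estimators_)
    return phi / k, base / k
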