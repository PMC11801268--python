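"""Exact path-dependent TreeSHAP for scikit-learn tree ensembles.

Computes Shapley-value feature attributions for a single decision tree in
polynomial time by carrying, down each root-to-leaf path, the proportion of
feature subsets of every size that would let the sample reach the node
("path-dependent" weighting: absent features are marginalized over the
tree's own training cover).  Attributions satisfy local accuracy exactly:
for every sample, ``base_value + sum(phi) == tree prediction`` up to float
rounding, and features a tree never splits on receive exactly zero.

Forest attributions are the average of per-tree attributions, matching the
probability-forest score (mean leaf class-1 fraction over trees).
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values", "forest_expected_value"]


def _extend(path: np.ndarray, depth: int, pz: float, po: float, pi: int) -> None:
    # path rows: (feature_index, zero_fraction, one_fraction, pweight)
    path[depth] = (pi, pz, po, 1.0 if depth == 0 else 0.0)
    for i in range(depth - 1, -1, -1):
        path[i + 1, 3] += po * path[i, 3] * (i + 1) / (depth + 1)
        path[i, 3] = pz * path[i, 3] * (depth - i) / (depth + 1)


def _unwind(path: np.ndarray, depth: int, idx: int) -> None:
    one = path[idx, 2]
    zero = path[idx, 1]
    nxt = path[depth, 3]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = path[i, 3]
            path[i, 3] = nxt * (depth + 1) / ((i + 1) * one)
            nxt = tmp - path[i, 3] * zero * (depth - i) / (depth + 1)
        else:
            path[i, 3] = path[i, 3] * (depth + 1) / (zero * (depth - i))
    for i in range(idx, depth):
        path[i, :3] = path[i + 1, :3]


def _unwound_sum(path: np.ndarray, depth: int, idx: int) -> float:
    one = path[idx, 2]
    zero = path[idx, 1]
    nxt = path[depth, 3]
    total = 0.0
    if one != 0.0:
        for i in range(depth - 1, -1, -1):
            tmp = nxt / ((i + 1) * one)
            total += tmp
            nxt = path[i, 3] - tmp * zero * (depth - i)
    else:
        for i in range(depth - 1, -1, -1):
            total += path[i, 3] / (zero * (depth - i))
    return total * (depth + 1)


def _leaf_values(tree, class_index: int | None) -> np.ndarray:
    value = tree.value
    if class_index is None:  # regressor (possibly multi-output; caller selects)
        return value[:, :, 0] if value.shape[2] == 1 else value[:, 0, :]
    v = value[:, 0, :]
    return v[:, class_index] / np.maximum(v.sum(axis=1), 1e-300)


def tree_shap_values(tree, X: np.ndarray, class_index: int | None = 1) -> np.ndarray:
    """Per-sample SHAP matrix (n, p) for one fitted sklearn tree.

    ``class_index`` selects the class-probability output for classifier
    trees; ``None`` treats the tree as a single-output regressor.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    left, right = tree.children_left, tree.children_right
    feature, threshold = tree.feature, tree.threshold
    weight = tree.weighted_n_node_samples
    vals = _leaf_values(tree, class_index)
    if vals.ndim > 1:
        raise ValueError("multi-output trees: select one output before attribution")

    phi_all = np.zeros((n, p))
    maxd = tree.max_depth + 2

    for s in range(n):
        x = X[s]
        phi = phi_all[s]

        def recurse(node: int, depth: int, parent_path: np.ndarray,
                    pz: float, po: float, pi: int) -> None:
            path = np.empty((maxd, 4))
            path[:depth] = parent_path[:depth]
            _extend(path, depth, pz, po, pi)
            if left[node] < 0:  # leaf
                v = vals[node]
                for i in range(1, depth + 1):
                    w = _unwound_sum(path, depth, i)
                    phi[int(path[i, 0])] += w * (path[i, 2] - path[i, 1]) * v
                return
            f = feature[node]
            hot, cold = (left[node], right[node]) if x[f] <= threshold[node] else (right[node], left[node])
            hot_z = weight[hot] / weight[node]
            cold_z = weight[cold] / weight[node]
            iz, io = 1.0, 1.0
            k = 0
            for i in range(1, depth + 1):
                if int(path[i, 0]) == f:
                    k = i
                    break
            d = depth
            if k > 0:
                iz, io = path[k, 1], path[k, 2]
                _unwind(path, d, k)
                d -= 1
            recurse(hot, d + 1, path, iz * hot_z, io, f)
            recurse(cold, d + 1, path, iz * cold_z, 0.0, f)

        recurse(0, 0, np.empty((maxd, 4)), 1.0, 1.0, -1)
    return phi_all


def tree_expected_value(tree, class_index: int | None = 1) -> float:
    """Training-cover expectation of the tree output (the SHAP base value)."""
    leaves = tree.children_left < 0
    w = tree.weighted_n_node_samples[leaves]
    v = _leaf_values(tree, class_index)[leaves]
    return float(np.sum(w * v) / w.sum())


def forest_shap_values(forest, X: np.ndarray, class_index: int | None = 1) -> tuple[np.ndarray, float]:
    """SHAP matrix and base value for a fitted sklearn forest.

    Returns ``(phi, base)`` with ``base + phi.sum(axis=1)`` equal to the
    forest's class-1 probability (classifier) or prediction (regressor).
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    for est in forest.estimators_:
        phi += tree_shap_values(est.tree_, X, class_index)
        base += tree_expected_value(est.tree_, class_index)
    k = len(forest.estimators_)
    return phi / k, base / k
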