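"""Exact path-dependent Shapley attributions for scikit-learn tree ensembles.

Implements the polynomial-time tree-traversal algorithm for Shapley values
of tree models (the "tree SHAP" recursion): for every root-to-leaf path the
algorithm maintains, per subset size, the summed Shapley weights of all
feature subsets that keep the path active, extending the path at each split
with the fractions of training cover that flow down each branch.  The
resulting attributions are exact Shapley values of the conditional
expectation defined by the tree's own cover distribution, and satisfy the
efficiency property

    sum_j phi_j(x) = f(x) - E[f]

per tree, where E[f] is the cover-weighted mean leaf value.  For a forest
the attributions and expectations average over trees.

Only binary-classification forests are needed here; ``class_index`` selects
which class probability is attributed.
"""

from __future__ import annotations

import sys

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values", "forest_expected_value"]


def _extend(m: list[list[float]], pz: float, po: float, pi: int) -> list[list[float]]:
    """Append a split (feature pi, zero/one fractions pz/po) to the path.

    Each entry of ``m`` is [feature, zero_fraction, one_fraction, weight];
    weights track, per subset size, the permutation weights of subsets of
    the path's features.
    """
    length = len(m)
    m = [e.copy() for e in m]
    m.append([pi, pz, po, 1.0 if length == 0 else 0.0])
    for i in range(length - 1, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / (length + 1)
        m[i][3] = pz * m[i][3] * (length - i) / (length + 1)
    return m


def _unwind(m: list[list[float]], idx: int) -> list[list[float]]:
    """Remove the split at ``idx``, undoing its effect on the weights."""
    length = len(m)
    m = [e.copy() for e in m]
    z, o = m[idx][1], m[idx][2]
    n = m[length - 1][3]
    for i in range(length - 2, -1, -1):
        if o != 0.0:
            tmp = m[i][3]
            m[i][3] = n * length / ((i + 1) * o)
            n = tmp - m[i][3] * z * (length - 1 - i) / length
        else:
            m[i][3] = m[i][3] * length / (z * (length - 1 - i))
    for i in range(idx, length - 1):
        m[i][0], m[i][1], m[i][2] = m[i + 1][0], m[i + 1][1], m[i + 1][2]
    return m[:-1]


def _leaf_values(tree, class_index: int | None) -> np.ndarray:
    """Per-node model output (class probability or regression value)."""
    value = tree.value  # (n_nodes, n_outputs, n_classes) or (n_nodes, n_outputs, 1)
    if class_index is None:
        return value[:, 0, 0].astype(float)
    v = value[:, 0, :].astype(float)
    totals = v.sum(axis=1)
    return v[:, class_index] / np.where(totals > 0, totals, 1.0)


def tree_shap_values(
    tree, X: np.ndarray, class_index: int | None = None
) -> tuple[np.ndarray, float]:
    """Shapley attributions for one fitted sklearn tree.

    ``tree`` is a ``DecisionTree*.tree_`` structure; returns
    (phi of shape (n_samples, n_features), expected value).
    """
    left, right = tree.children_left, tree.children_right
    feature, threshold = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    values = _leaf_values(tree, class_index)

    # cover-weighted expectation of the model output
    is_leaf = left == -1
    base = float(np.sum(cover[is_leaf] * values[is_leaf]) / cover[0])

    n_samples, n_features = X.shape
    phi = np.zeros((n_samples, n_features))
    depth_guard = int(tree.max_depth) * 2 + 10
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, depth_guard + 1000))
    try:
        for s in range(n_samples):
            x = X[s]
            out = phi[s]

            def recurse(node: int, m: list[list[float]], pz: float, po: float, pi: int) -> None:
                m = _extend(m, pz, po, pi)
                if left[node] == -1:
                    v = values[node]
                    for i in range(1, len(m)):
                        w = sum(e[3] for e in _unwind(m, i))
                        out[m[i][0]] += w * (m[i][2] - m[i][1]) * v
                    return
                f = feature[node]
                hot, cold = (
                    (left[node], right[node])
                    if x[f] <= threshold[node]
                    else (right[node], left[node])
                )
                iz = io = 1.0
                k = next((i for i in range(1, len(m)) if m[i][0] == f), None)
                if k is not None:
                    iz, io = m[k][1], m[k][2]
                    m = _unwind(m, k)
                r = cover[node]
                recurse(hot, m, iz * cover[hot] / r, io, f)
                recurse(cold, m, iz * cover[cold] / r, 0.0, f)

            recurse(0, [], 1.0, 1.0, -1)
    finally:
        sys.setrecursionlimit(old_limit)
    return phi, base


def forest_shap_values(
    forest, X: np.ndarray, class_index: int = 1
) -> tuple[np.ndarray, float]:
    """Average Shapley attributions of ``predict_proba[:, class_index]``.

    Returns (phi of shape (n_samples, n_features), base value); the
    efficiency identity phi.sum(axis=1) + base == predict_proba holds to
    floating-point accuracy.
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros_like(X, dtype=float)
    base = 0.0
    for est in forest.estimators_:
        p, b = tree_shap_values(est.tree_, X, class_index=class_index)
        phi += p
        base += b
    k = len(forest.estimators_)
    return phi / k, base / k


def forest_expected_value(forest, class_index: int = 1) -> float:
    """Cover-weighted expected class probability of the ensemble."""
    bases = []
    for est in forest.estimators_:
        t = est.tree_
        is_leaf = t.children_left == -1
        v = _leaf_values(t, class_index)
        bases.append(np.sum(t.weighted_n_node_samples[is_leaf] * v[is_leaf]) / t.weighted_n_node_samples[0])
    return float(np.mean(bases))
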