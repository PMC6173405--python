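"""Independent brute-force re-implementations used as oracles in tests.

These walk the fitted tree structures directly (recursive threshold descent)
and apply the leaf-membership weight formula literally, sharing no code with
the vectorised implementation under test.
"""

import numpy as np


def route_leaf(sk_tree, x):
    """Recursive-descent routing: <= threshold goes left."""
    t = sk_tree.tree_
    node = 0
    while t.children_left[node] != -1:
        if x[t.feature[node]] <= t.threshold[node]:
            node = t.children_left[node]
        else:
            node = t.children_right[node]
    return node


def brute_tree_weights(tree, x, X):
    """w_i(x, tree) = I(X_i in leaf(x)) / #leaf members, with bootstrap multiplicity."""
    n = X.shape[0]
    lx = route_leaf(tree.sk, x)
    members = [i for i in tree.bootstrap_indices if route_leaf(tree.sk, X[i]) == lx]
    w = np.zeros(n)
    for i in members:
        w[i] += 1.0 / len(members)
    return w


def brute_forest_weights(forest, x):
    w = np.zeros(forest.n)
    for tree in forest.trees:
        w += brute_tree_weights(tree, x, forest.data.X)
    return w / forest.T


def brute_quantile(y, w, tau):
    """inf{y : sum_i w_i I(Y_i <= y) >= tau} by scanning the sorted support."""
    for val in np.sort(np.unique(y)):
        if w[y <= val].sum() >= tau - 1e-12:
            return val
    return np.max(y)


def brute_levene(groups, centering="mean"):
    """Textbook Levene W statistic computed with plain loops."""
    center = np.mean if centering == "mean" else np.median
    Z = [[abs(v - center(g)) for v in g] for g in groups]
    g = len(Z)
    N = sum(len(z) for z in Z)
    zbar_i = [sum(z) / len(z) for z in Z]
    zbar = sum(sum(z) for z in Z) / N
    num = sum(len(z) * (zb - zbar) ** 2 for z, zb in zip(Z, zbar_i))
    den = sum((v - zb) ** 2 for z, zb in zip(Z, zbar_i) for v in z)
    return (N - g) / (g - 1) * num / den
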