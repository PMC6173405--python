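"""Bagged CART regression forest with bootstrap/OOB bookkeeping.

This is the shared engine for both the variable-selection forest (stage 2) and
the quantile regression forest (stage 3).  Individual trees are grown by
scikit-learn's :class:`~sklearn.tree.DecisionTreeRegressor` (variance-reduction
splits, midpoint thresholds, ``<=`` routes left, nodes with fewer than
``min_node`` samples are not split, ``mtry`` features drawn per node); around
each tree this module keeps the bookkeeping that quantile estimation needs and
that a plain regressor discards:

* the bootstrap multiset each tree was grown on (a sample drawn twice counts
  twice in leaf weights),
* the out-of-bag (OOB) index set, i.e. the samples absent from the bootstrap,
* the leaf assignment of every bootstrap draw, from which per-leaf membership
  counts and hence the QRF weights are derived.

Forests are reproducible: every tree's bootstrap sample, split randomisation
and permutation-importance shuffles derive deterministically from the forest
seed via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .io import Dataset

__all__ = [
    "Tree",
    "Forest",
    "ImportanceVector",
    "fit_tree",
    "fit_forest",
    "apply_tree",
    "permutation_importance",
    "select_by_importance",
]


@dataclass
class Tree:
    """One un-pruned regression tree plus its bootstrap/OOB bookkeeping."""

    sk: DecisionTreeRegressor
    bootstrap_indices: np.ndarray  # (n,) training indices drawn with replacement
    oob_indices: np.ndarray  # sorted complement of the distinct bootstrap indices
    bs_leaf: np.ndarray  # leaf node id of each bootstrap draw
    leaf_counts: np.ndarray  # bincount of bs_leaf (bootstrap members per leaf)
    seed: int

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id for each row of ``X`` (deterministic threshold routing)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.isfinite(X).all():
            raise ValueError("cannot route non-finite feature values through a tree")
        return self.sk.apply(X)

    @property
    def n_leaves(self) -> int:
        return int(self.sk.get_n_leaves())

    def leaf_members(self, leaf_id: int) -> np.ndarray:
        """Training indices in the leaf, with bootstrap multiplicity."""
        return self.bootstrap_indices[self.bs_leaf == leaf_id]


@dataclass
class Forest:
    """A list of trees grown on bootstrap samples of one training Dataset."""

    trees: list[Tree]
    data: Dataset
    T: int
    m: int
    min_node: int
    seed: int

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def M(self) -> int:
        return self.data.M

    @property
    def y(self) -> np.ndarray:
        return self.data.y


@dataclass
class ImportanceVector:
    """Permutation importance per feature (mean OOB MSE increase, units y^2)."""

    feature_ids: list[str]
    importance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_ids, "importance": self.importance}
        )

    def ranked(self) -> pd.DataFrame:
        df = self.to_frame()
        return df.sort_values(
            ["importance", "feature_id"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)


def default_mtry(M: int) -> int:
    """The m = M/3 rule (floored, at least 1)."""
    return max(1, M // 3)


def fit_tree(
    data: Dataset,
    bootstrap_indices: np.ndarray,
    m: int,
    min_node: int,
    rng: np.random.Generator,
) -> Tree:
    """Grow one un-pruned CART regression tree on the given bootstrap multiset.

    At each node ``m`` candidate features are drawn; the split minimising the
    summed child response variance is taken; nodes with fewer than ``min_node``
    samples, pure nodes, and nodes with no valid split become leaves.
    """
    bootstrap_indices = np.asarray(bootstrap_indices, dtype=np.intp)
    if bootstrap_indices.size == 0:
        raise ValueError("empty bootstrap sample")
    if not 1 <= m <= data.M:
        raise ValueError(f"m must lie in [1, {data.M}], got {m}")
    if min_node < 2:
        raise ValueError("min_node must be >= 2")
    seed = int(rng.integers(0, 2**31 - 1))
    sk = DecisionTreeRegressor(
        criterion="squared_error",
        splitter="best",
        max_features=m,
        min_samples_split=min_node,
        random_state=seed,
    )
    Xb = data.X[bootstrap_indices]
    sk.fit(Xb, data.y[bootstrap_indices])
    bs_leaf = sk.apply(Xb)
    oob = np.setdiff1d(np.arange(data.n), bootstrap_indices, assume_unique=False)
    return Tree(
        sk=sk,
        bootstrap_indices=bootstrap_indices,
        oob_indices=oob,
        bs_leaf=bs_leaf,
        leaf_counts=np.bincount(bs_leaf),
        seed=seed,
    )


def fit_forest(
    data: Dataset,
    T: int,
    m: int | None = None,
    min_node: int = 10,
    seed: int = 0,
) -> Forest:
    """Fit ``T`` independent bootstrap trees with per-tree RNGs spawned from ``seed``."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if m is None:
        m = default_mtry(data.M)
    children = np.random.SeedSequence(seed).spawn(T)
    trees: list[Tree] = []
    for t in range(T):
        rng = np.random.default_rng(children[t])
        bootstrap = rng.integers(0, data.n, size=data.n)
        trees.append(fit_tree(data, bootstrap, m=m, min_node=min_node, rng=rng))
    return Forest(trees=trees, data=data, T=T, m=m, min_node=min_node, seed=seed)


def apply_tree(tree: Tree, x: np.ndarray) -> int:
    """Leaf node id containing the single sample ``x``."""
    return int(tree.apply(np.asarray(x, dtype=float))[0])


def permutation_importance(
    forest: Forest, data: Dataset, seed: int = 0
) -> ImportanceVector:
    """OOB permutation importance, averaged over trees.

    Per tree: baseline OOB mean squared error of the tree's leaf-mean
    predictions; then, for each feature used by the tree, the feature's values
    are permuted among that tree's OOB samples and the MSE increase recorded.
    Features a tree never splits on contribute exactly 0 for that tree.  Trees
    without OOB samples are skipped with a warning.
    """
    if data is not forest.data and data.feature_ids != forest.data.feature_ids:
        raise ValueError("importance must be computed on the forest's training data")
    n, M = data.n, data.M
    children = np.random.SeedSequence(seed).spawn(len(forest.trees))
    increase = np.zeros(M)
    contributing = 0
    for t, tree in enumerate(forest.trees):
        oob = tree.oob_indices
        if oob.size == 0:
            warnings.warn(
                f"tree {t} has no OOB samples; skipped in permutation importance",
                stacklevel=2,
            )
            continue
        contributing += 1
        rng = np.random.default_rng(children[t])
        Xo = data.X[oob]
        yo = data.y[oob]
        base_mse = float(np.mean((yo - tree.sk.predict(Xo)) ** 2))
        used = np.unique(tree.sk.tree_.feature)
        used = set(used[used >= 0].tolist())
        Xp = Xo.copy()
        for f in range(M):
            if f not in used:
                continue  # permutation is a no-op: exact 0 contribution
            perm = rng.permutation(oob.size)
            Xp[:, f] = Xo[perm, f]
            mse = float(np.mean((yo - tree.sk.predict(Xp)) ** 2))
            Xp[:, f] = Xo[:, f]
            increase[f] += mse - base_mse
    if contributing == 0:
        raise ValueError("no tree has OOB samples; cannot compute importance")
    return ImportanceVector(
        feature_ids=list(data.feature_ids), importance=increase / contributing
    )


def select_by_importance(imp: ImportanceVector, c: float = 2.0) -> list[str]:
    """Features whose importance exceeds mean + c * SD of all importances.

    SD is the sample standard deviation (n-1 denominator).  The returned IDs are
    ordered by importance descending (ties by feature ID).  Raises if nothing
    passes, with a hint to lower ``c``.
    """
    values = np.asarray(imp.importance, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 features to apply the importance cutoff")
    cutoff = values.mean() + c * values.std(ddof=1)
    mask = values > cutoff
    if not mask.any():
        raise ValueError(
            f"no feature exceeds the importance cutoff mean + {c}*SD = {cutoff:.6g}; "
            "lower c to select features"
        )
    order = np.lexsort((np.array(imp.feature_ids, dtype=object)[mask], -values[mask]))
    picked = np.array(imp.feature_ids, dtype=object)[mask][order]
    return [str(f) for f in picked]
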