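"""Quantile regression forest: conditional CDF, quantile/mean prediction, OOB.

A fitted forest assigns each query point x a weight vector over the training
samples: within each tree, the bootstrap members of the leaf containing x share
weight uniformly (with bootstrap multiplicity),

    w_i(x, tree) = I(X_i in leaf(x)) / #{bootstrap members of leaf(x)},

and the forest weight is the average over trees, w_i(x) = (1/T) sum_t w_i(x, t).
The estimated conditional CDF is the weighted empirical distribution
F_hat(y | x) = sum_i w_i(x) I(Y_i <= y), quantiles are read off by
q_tau = inf{y : F_hat(y|x) >= tau}, and the conditional mean is sum_i w_i(x) Y_i.

Out-of-bag prediction averages, for training sample i, the tree weights over
exactly those trees in which i was not drawn into the bootstrap (dividing by the
number of such trees); samples that are in-bag everywhere receive NaN sentinels.

The module also houses the statsmodels-style model front end:
:class:`QuantileRegressionForest` (construct from arrays or a Dataset) whose
``fit`` returns a :class:`QRFResults` carrying predictions, OOB diagnostics,
prediction intervals and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .forest import Forest, Tree, fit_forest
from .io import Dataset

__all__ = [
    "DEFAULT_TAUS",
    "ConditionalCDF",
    "PredictionInterval",
    "tree_weights",
    "forest_weights",
    "conditional_cdf",
    "predict_quantile",
    "predict_mean",
    "oob_weights",
    "oob_predict",
    "prediction_interval",
    "QuantileRegressionForest",
    "QRFResults",
]

#: quantile grid reported by default
DEFAULT_TAUS = (0.025, 0.1, 0.25, 0.5, 0.75, 0.9, 0.975)

#: tolerance absorbing floating-point drift in the cumulative weights
_CDF_TOL = 1e-12


# ---------------------------------------------------------------------------
# weight vectors
# ---------------------------------------------------------------------------

def _tree_weight_rows(tree: Tree, leaves: np.ndarray, n: int) -> np.ndarray:
    """Dense (len(leaves) x n) weight rows of one tree for pre-applied leaf ids."""
    W = np.zeros((leaves.size, n))
    mask = tree.bs_leaf[None, :] == leaves[:, None]
    rows, draws = np.nonzero(mask)
    vals = 1.0 / tree.leaf_counts[tree.bs_leaf[draws]]
    np.add.at(W, (rows, tree.bootstrap_indices[draws]), vals)
    return W


def tree_weights(tree: Tree, x: np.ndarray, n: int) -> np.ndarray:
    """Weight vector of a single tree at x (uniform over leaf co-members)."""
    leaf = tree.apply(np.asarray(x, dtype=float))
    return _tree_weight_rows(tree, leaf, n)[0]


def forest_weight_matrix(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Forest weight vectors for each row of ``X`` (rows sum to 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.zeros((X.shape[0], forest.n))
    for tree in forest.trees:
        W += _tree_weight_rows(tree, tree.apply(X), forest.n)
    W /= forest.T
    return W


def forest_weights(forest: Forest, x: np.ndarray) -> np.ndarray:
    """Average of the per-tree weight vectors at a single point x."""
    return forest_weight_matrix(forest, np.asarray(x, dtype=float)[None, :])[0]


def oob_weights(forest: Forest) -> tuple[np.ndarray, np.ndarray]:
    """Per-training-sample OOB weight matrix and OOB-eligible tree counts.

    Row i averages tree weights over the trees where sample i is out-of-bag
    (dividing by the count of such trees, not T).  Rows of samples that are
    never OOB are all-zero; the returned counts identify them.
    """
    n = forest.n
    W = np.zeros((n, n))
    counts = np.zeros(n, dtype=int)
    for tree in forest.trees:
        oob = tree.oob_indices
        if oob.size == 0:
            continue
        W[oob] += _tree_weight_rows(tree, tree.apply(forest.data.X[oob]), n)
        counts[oob] += 1
    eligible = counts > 0
    W[eligible] /= counts[eligible, None]
    return W, counts


# ---------------------------------------------------------------------------
# CDF / quantiles / mean from weight vectors
# ---------------------------------------------------------------------------

@dataclass
class ConditionalCDF:
    """Weighted step-function estimate of F(y | X = x)."""

    support: np.ndarray  # sorted distinct training responses
    cdf: np.ndarray  # nondecreasing, ends at 1

    def evaluate(self, y: float | np.ndarray) -> np.ndarray:
        """F_hat(y): total weight of training responses <= y (right-continuous)."""
        idx = np.searchsorted(self.support, np.asarray(y, dtype=float), side="right")
        padded = np.concatenate(([0.0], self.cdf))
        return padded[idx]

    def quantile(self, tau: float | Sequence[float]) -> np.ndarray | float:
        taus = np.atleast_1d(np.asarray(tau, dtype=float))
        _check_taus(taus)
        idx = np.minimum(
            np.searchsorted(self.cdf, taus - _CDF_TOL, side="left"),
            self.support.size - 1,
        )
        out = self.support[idx]
        return float(out[0]) if np.isscalar(tau) or np.ndim(tau) == 0 else out


def _check_taus(taus: np.ndarray) -> None:
    if np.any((taus <= 0) | (taus >= 1)):
        raise ValueError("quantile levels tau must lie strictly in (0, 1)")


def weighted_quantiles(
    y: np.ndarray, W: np.ndarray, taus: Sequence[float]
) -> np.ndarray:
    """q_tau = inf{y : cumulative weight >= tau} for each weight row.

    Rows whose weights do not sum to ~1 (the all-zero OOB sentinel) yield NaN.
    """
    y = np.asarray(y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    taus = np.asarray(taus, dtype=float)
    _check_taus(taus)
    order = np.argsort(y, kind="stable")
    ys = y[order]
    cum = np.cumsum(W[:, order], axis=1)
    valid = np.abs(cum[:, -1] - 1.0) <= 1e-6
    out = np.full((W.shape[0], taus.size), np.nan)
    for j, tau in enumerate(taus):
        idx = np.minimum((cum < tau - _CDF_TOL).sum(axis=1), y.size - 1)
        out[:, j] = ys[idx]
    out[~valid] = np.nan
    return out


def conditional_cdf(forest: Forest, x: np.ndarray) -> ConditionalCDF:
    """The weighted ECDF of training responses at the query point x."""
    w = forest_weights(forest, x)
    order = np.argsort(forest.y, kind="stable")
    ys = forest.y[order]
    ws = w[order]
    support, start = np.unique(ys, return_index=True)
    totals = np.add.reduceat(ws, start)
    cdf = np.minimum(np.cumsum(totals), 1.0)
    cdf[-1] = 1.0
    return ConditionalCDF(support=support, cdf=cdf)


def predict_quantile(
    forest: Forest, x: np.ndarray, tau: float | Sequence[float]
) -> float | np.ndarray:
    """Conditional quantile(s) at x; a tau list reuses a single weight vector."""
    taus = np.atleast_1d(np.asarray(tau, dtype=float))
    w = forest_weights(forest, x)
    out = weighted_quantiles(forest.y, w[None, :], taus)[0]
    return float(out[0]) if np.ndim(tau) == 0 else out


def predict_mean(forest: Forest, x: np.ndarray) -> float:
    """Conditional mean sum_i w_i(x) Y_i at x."""
    return float(forest_weights(forest, x) @ forest.y)


@dataclass(frozen=True)
class PredictionInterval:
    """Central (1 - alpha) prediction interval [q_{alpha/2}, q_{1-alpha/2}]."""

    lower: float
    upper: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if np.isfinite(self.lower) and np.isfinite(self.upper) and self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, y: float) -> bool:
        return bool(self.lower <= y <= self.upper)


def prediction_interval(
    forest: Forest, x: np.ndarray, alpha: float = 0.05
) -> PredictionInterval:
    """Prediction interval from the alpha/2 and 1-alpha/2 conditional quantiles."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lo, hi = predict_quantile(forest, x, [alpha / 2, 1 - alpha / 2])
    return PredictionInterval(lower=float(lo), upper=float(hi), alpha=alpha)


def oob_predict(
    forest: Forest,
    taus: Sequence[float] = DEFAULT_TAUS,
    include_mean: bool = True,
) -> pd.DataFrame:
    """Out-of-bag quantile (and mean) predictions for every training sample.

    Samples never out-of-bag get NaN in every column, with a warning; columns
    are named ``q0.025`` etc. plus ``mean``.
    """
    taus = np.asarray(taus, dtype=float)
    _check_taus(taus)
    W, counts = oob_weights(forest)
    never = counts == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} of {forest.n} samples were in-bag in every tree; "
            "their OOB predictions are NaN (increase T)",
            stacklevel=2,
        )
    Q = weighted_quantiles(forest.y, W, taus)
    data = {f"q{tau:g}": Q[:, j] for j, tau in enumerate(taus)}
    if include_mean:
        mean = W @ forest.y
        mean[never] = np.nan
        data = {"mean": mean, **data}
    return pd.DataFrame(data, index=pd.Index(forest.data.sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# model / results front end
# ---------------------------------------------------------------------------

class QuantileRegressionForest:
    """Quantile regression forest model for one drug's response.

    Parameters
    ----------
    y : array-like, shape (n,)
        Drug response (activity area) per sample.
    X : array-like, shape (n, M)
        Genomic feature matrix aligned with ``y``.
    n_trees : int
        Number of bootstrap trees T (the reference analysis uses 15000; far
        fewer suffice for small panels).
    mtry : int, optional
        Features drawn per split; defaults to the M/3 rule.
    min_node : int
        Nodes with fewer samples than this are not split (default 10).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        *,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
        n_trees: int = 15000,
        mtry: int | None = None,
        min_node: int = 10,
    ) -> None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if feature_ids is None:
            feature_ids = [f"x{j}" for j in range(X.shape[1])]
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(X.shape[0])]
        self.data = Dataset(X, y, list(sample_ids), list(feature_ids))
        self.n_trees = int(n_trees)
        self.mtry = mtry
        self.min_node = int(min_node)

    @classmethod
    def from_dataset(cls, data: Dataset, **kwargs) -> "QuantileRegressionForest":
        return cls(
            data.y,
            data.X,
            feature_ids=data.feature_ids,
            sample_ids=data.sample_ids,
            **kwargs,
        )

    def fit(self, seed: int = 0) -> "QRFResults":
        forest = fit_forest(
            self.data,
            T=self.n_trees,
            m=self.mtry,
            min_node=self.min_node,
            seed=seed,
        )
        return QRFResults(model=self, forest=forest, seed=seed)


@dataclass
class QRFResults:
    """Fitted QRF: point/quantile prediction, intervals, OOB diagnostics."""

    model: QuantileRegressionForest
    forest: Forest
    seed: int
    _oob_cache: dict = field(default_factory=dict, repr=False)

    # -- prediction on arbitrary samples ------------------------------------
    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        W = forest_weight_matrix(self.forest, X)
        return W @ self.forest.y

    def predict_quantiles(
        self, X: np.ndarray, taus: Sequence[float] = DEFAULT_TAUS
    ) -> pd.DataFrame:
        taus = np.asarray(taus, dtype=float)
        W = forest_weight_matrix(self.forest, X)
        Q = weighted_quantiles(self.forest.y, W, taus)
        return pd.DataFrame(Q, columns=[f"q{t:g}" for t in taus])

    def prediction_intervals(self, X: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        q = self.predict_quantiles(X, [alpha / 2, 1 - alpha / 2]).to_numpy()
        return pd.DataFrame(
            {"lower": q[:, 0], "upper": q[:, 1], "length": q[:, 1] - q[:, 0]}
        )

    def conditional_cdf(self, x: np.ndarray) -> ConditionalCDF:
        return conditional_cdf(self.forest, x)

    # -- out-of-bag ----------------------------------------------------------
    def oob_predictions(
        self, taus: Sequence[float] = DEFAULT_TAUS, include_mean: bool = True
    ) -> pd.DataFrame:
        key = (tuple(np.asarray(taus, dtype=float)), include_mean)
        if key not in self._oob_cache:
            self._oob_cache[key] = oob_predict(self.forest, taus, include_mean)
        return self._oob_cache[key]

    def oob_accuracy(self, kind: str = "mean") -> float:
        """Pearson correlation of observed responses with OOB predictions."""
        oob = self.oob_predictions()
        col = "mean" if kind == "mean" else "q0.5"
        return _metrics.accuracy(self.forest.y, oob[col].to_numpy())

    def oob_interval_metrics(self, alpha: float = 0.05) -> "_metrics.IntervalMetrics":
        lo, hi = alpha / 2, 1 - alpha / 2
        oob = self.oob_predictions(taus=(lo, hi), include_mean=False)
        return _metrics.evaluate_intervals(
            self.forest.y, (oob[f"q{lo:g}"].to_numpy(), oob[f"q{hi:g}"].to_numpy())
        )

    def oob_quantile_errors(
        self, taus: Sequence[float] = DEFAULT_TAUS
    ) -> pd.DataFrame:
        oob = self.oob_predictions(taus=taus, include_mean=False)
        return _metrics.evaluate_quantiles(self.forest.y, oob.to_numpy(), taus)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        f = self.forest
        lines = [
            "Quantile Regression Forest Results",
            "=" * 46,
            f"No. samples:        {f.n}",
            f"No. features:       {f.M}",
            f"Trees (T):          {f.T}",
            f"mtry (m):           {f.m}",
            f"Min node size:      {f.min_node}",
            f"Seed:               {self.seed}",
            "-" * 46,
        ]
        try:
            acc_mean = self.oob_accuracy("mean")
            acc_med = self.oob_accuracy("median")
            lines += [
                f"OOB accuracy (mean prediction):    r = {acc_mean:.4f}",
                f"OOB accuracy (median prediction):  r = {acc_med:.4f}",
            ]
            for alpha, label in ((0.05, "95%"), (0.2, "80%")):
                im = self.oob_interval_metrics(alpha)
                lines.append(
                    f"{label} PI: AveL = {im.average_length:.4f}, "
                    f"CP = {im.coverage_probability:.4f}"
                )
        except ValueError as exc:  # degenerate data: report what we can
            lines.append(f"OOB diagnostics unavailable: {exc}")
        lines.append("=" * 46)
        return "\n".join(lines)
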