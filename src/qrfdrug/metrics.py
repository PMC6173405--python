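"""Evaluation metrics: check loss, quantile prediction error, interval metrics.

The quantile (check/pinball) loss rho_tau(r) = tau*r - r*I(r < 0) scores a
tau-quantile prediction by its residual r = y - q_hat; its expectation is
minimised by the true tau-quantile.  Prediction intervals are summarised by
their average length (AveL) and empirical coverage probability (CP, closed
interval), and point predictions by the Pearson correlation between observed
and predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntervalMetrics",
    "quantile_loss",
    "evaluate_quantiles",
    "evaluate_intervals",
    "accuracy",
]


@dataclass(frozen=True)
class IntervalMetrics:
    average_length: float
    coverage_probability: float

    def __post_init__(self) -> None:
        if not 0 <= self.coverage_probability <= 1:
            raise ValueError("coverage probability must lie in [0, 1]")


def quantile_loss(r: float | np.ndarray, tau: float) -> float | np.ndarray:
    """rho_tau(r) = tau*r if r >= 0 else (tau-1)*r; always nonnegative."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie strictly in (0, 1)")
    r = np.asarray(r, dtype=float)
    out = np.where(r >= 0, tau * r, (tau - 1.0) * r)
    return float(out) if out.ndim == 0 else out


def evaluate_quantiles(
    observed: np.ndarray,
    predicted_quantiles: np.ndarray,
    taus: Sequence[float],
) -> pd.DataFrame:
    """Mean (MPE) and sample SD of rho_tau(Y - q_hat_tau) per quantile level.

    NaN predictions (OOB sentinels) are dropped per column; a column with no
    defined predictions raises.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    Q = np.atleast_2d(np.asarray(predicted_quantiles, dtype=float))
    taus = np.asarray(taus, dtype=float)
    if Q.shape != (observed.size, taus.size):
        raise ValueError(
            f"predicted_quantiles shape {Q.shape} does not match "
            f"{observed.size} observations x {taus.size} quantile levels"
        )
    rows = []
    for j, tau in enumerate(taus):
        ok = np.isfinite(Q[:, j]) & np.isfinite(observed)
        if not ok.any():
            raise ValueError(f"no defined predictions for tau={tau:g}")
        losses = quantile_loss(observed[ok] - Q[ok, j], tau)
        sd = float(np.std(losses, ddof=1)) if ok.sum() > 1 else 0.0
        rows.append({"tau": tau, "MPE": float(np.mean(losses)), "SD": sd, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def _interval_bounds(intervals) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(intervals, pd.DataFrame):
        return intervals["lower"].to_numpy(float), intervals["upper"].to_numpy(float)
    if isinstance(intervals, tuple) and len(intervals) == 2:
        return (
            np.asarray(intervals[0], dtype=float).ravel(),
            np.asarray(intervals[1], dtype=float).ravel(),
        )
    lower = np.array([iv.lower for iv in intervals], dtype=float)
    upper = np.array([iv.upper for iv in intervals], dtype=float)
    return lower, upper


def evaluate_intervals(observed: np.ndarray, intervals) -> IntervalMetrics:
    """AveL and CP of prediction intervals (closed-interval coverage).

    ``intervals`` may be a list of PredictionInterval, a (lower, upper) tuple of
    arrays, or a DataFrame with ``lower``/``upper`` columns.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    lower, upper = _interval_bounds(intervals)
    if lower.size != observed.size:
        raise ValueError("need exactly one interval per observation")
    ok = np.isfinite(lower) & np.isfinite(upper) & np.isfinite(observed)
    if not ok.any():
        raise ValueError("no defined intervals")
    lower, upper, observed = lower[ok], upper[ok], observed[ok]
    covered = (lower <= observed) & (observed <= upper)
    return IntervalMetrics(
        average_length=float(np.mean(upper - lower)),
        coverage_probability=float(np.mean(covered)),
    )


def accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values.

    NaN pairs are dropped; requires at least 3 defined pairs and nonzero
    variance on both sides.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same length")
    ok = np.isfinite(observed) & np.isfinite(predicted)
    if ok.sum() < 3:
        raise ValueError("accuracy requires at least 3 defined pairs")
    o, p = observed[ok], predicted[ok]
    if np.ptp(o) == 0 or np.ptp(p) == 0:
        raise ValueError("zero variance in observed or predicted values")
    return float(np.corrcoef(o, p)[0, 1])
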