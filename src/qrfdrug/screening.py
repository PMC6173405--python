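"""Stage 1: marginal feature screening by Pearson correlation with the response.

Each feature is tested for linear association with the drug response using the
two-sided t-test on the Pearson correlation coefficient,

    t = r * sqrt((n - 2) / (1 - r^2))  ~  t(n - 2)  under H0: rho = 0,

and features with raw p < alpha_screen (default 0.05) are retained.  No
multiple-testing correction is applied: the screen is a deliberately permissive
pre-filter, not an inference procedure.  Binary mutation features go through the
same formula (point-biserial correlation).  Degenerate features with fewer than
two distinct values are assigned r = 0, p = 1 and can never be selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "pearson_test", "screen_features"]


@dataclass
class ScreenResult:
    """Per-feature correlation, p-value and selection mask from the screen."""

    feature_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    selected: np.ndarray
    alpha_screen: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selected_ids(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        """Screening report in original feature order."""
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "r": self.r,
                "p": self.p,
                "selected": self.selected,
            }
        )

    def ranked(self) -> pd.DataFrame:
        """Report ranked by p ascending, ties broken by |r| descending then ID."""
        df = self.to_frame()
        df["abs_r"] = np.abs(df["r"])
        df = df.sort_values(
            ["p", "abs_r", "feature_id"], ascending=[True, False, True], kind="stable"
        ).drop(columns="abs_r")
        return df.reset_index(drop=True)


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of the t-test for a Pearson correlation."""
    r = np.clip(r, -1.0, 1.0)
    p = np.empty_like(r, dtype=float)
    exact = np.abs(r) >= 1.0 - 1e-15
    p[exact] = 0.0
    rr = r[~exact]
    t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p[~exact] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return p


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of one feature with the response and its two-sided p.

    Conventions: a constant x gives (r=0, p=1); |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("pearson_test requires n >= 3")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    if np.ptp(x) == 0:
        return 0.0, 1.0
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    p = float(_pearson_p(np.array([r]), n)[0])
    return r, p


def screen_features(data: Dataset, alpha_screen: float = 0.05) -> ScreenResult:
    """Apply ``pearson_test`` to every feature column of ``data``.

    Raises if not a single feature passes, with a hint to relax the threshold.
    """
    if not 0 < alpha_screen <= 1:
        raise ValueError("alpha_screen must lie in (0, 1]")
    X, y = data.X, data.y
    n = data.n
    if n < 3:
        raise ValueError("screening requires n >= 3")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")

    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    degenerate = sxx <= 0
    sxx_safe = np.where(degenerate, 1.0, sxx)
    r = (xc.T @ yc) / np.sqrt(sxx_safe * (yc @ yc))
    r[degenerate] = 0.0
    r = np.clip(r, -1.0, 1.0)
    p = _pearson_p(r, n)
    p[degenerate] = 1.0
    selected = p < alpha_screen

    logger.info(
        "screening: %d of %d features selected at alpha=%g (n=%d)",
        int(selected.sum()), data.M, alpha_screen, n,
    )
    if not selected.any():
        raise ValueError(
            f"no feature passed screening at alpha_screen={alpha_screen}; "
            "relax alpha_screen to retain features"
        )
    return ScreenResult(
        feature_ids=list(data.feature_ids),
        r=r,
        p=p,
        selected=selected,
        alpha_screen=float(alpha_screen),
    )
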