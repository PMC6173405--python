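"""Prediction-reliability comparison via inverse-transform sampling + Levene test.

A fitted QRF gives each subject (cell line / patient) an estimated conditional
quantile function of drug response.  Drawing tau_1..tau_k ~ U(0,1) and reading
off q_hat_tau yields k pseudo-responses per subject — inverse transform sampling
from the forest's conditional law.  The Levene test for homogeneity of variances
(robust to non-normal samples) then compares subjects' response variability:

    H0: sigma_1^2 = sigma_2^2   vs   H1: sigma_1^2 != sigma_2^2,

with the statistic computed from absolute deviations Z_ij = |Y*_ij - center_i|,

    W = (N - g)/(g - 1) * sum_i n_i (Zbar_i - Zbar)^2 / sum_ij (Z_ij - Zbar_i)^2,

referred to an F(g-1, N-g) upper tail.  Classic mean centering is the default;
median centering (Brown-Forsythe) is exposed as an option.  At near-equal point
predictions, the subject or drug with the shorter prediction interval offers the
more stable (reliable) response, and a rejecting Levene test backs that reading
statistically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forest import Forest
from .qrf import forest_weights, weighted_quantiles

__all__ = [
    "ResponseSample",
    "LeveneResult",
    "ComparisonReport",
    "sample_response",
    "levene_test",
    "compare_reliability",
]


@dataclass
class ResponseSample:
    """k pseudo drug responses for one subject, drawn from the forest's F_hat."""

    values: np.ndarray
    source: str
    seed: int


def sample_response(
    forest: Forest, x: np.ndarray, k: int = 500, seed: int = 0, source: str = ""
) -> ResponseSample:
    """Inverse-transform sample of size k from the conditional law at x.

    tau_j are drawn i.i.d. U(0,1) (seeded, independent per call) and mapped
    through q_hat_tau; every value lies within the training response range.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    taus = rng.uniform(0.0, 1.0, size=k)
    taus = np.clip(taus, 1e-12, 1 - 1e-12)
    w = forest_weights(forest, x)
    values = weighted_quantiles(forest.y, w[None, :], taus)[0]
    return ResponseSample(values=values, source=source, seed=seed)


@dataclass
class LeveneResult:
    statistic: float
    p_value: float
    group_variances: np.ndarray
    df: tuple[int, int]
    alpha: float
    reject: bool


def levene_test(
    groups: Sequence[np.ndarray],
    centering: str = "mean",
    alpha: float = 0.05,
) -> LeveneResult:
    """Levene homogeneity-of-variances test for g >= 2 groups.

    Degenerate conventions: if every absolute deviation is identical (within and
    across groups) the statistic is 0 and p = 1; if groups' mean deviations
    differ but within-group variability is exactly zero, p = 0.
    """
    if centering not in {"mean", "median"}:
        raise ValueError("centering must be 'mean' or 'median'")
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
        if not np.isfinite(g).all():
            raise ValueError("groups must contain finite values only")

    center = np.mean if centering == "mean" else np.median
    Z = [np.abs(g - center(g)) for g in gs]
    n_i = np.array([z.size for z in Z])
    N = int(n_i.sum())
    g_n = len(Z)
    zbar_i = np.array([z.mean() for z in Z])
    zbar = float(np.concatenate(Z).mean())
    between = float(np.sum(n_i * (zbar_i - zbar) ** 2))
    within = float(sum(((z - zb) ** 2).sum() for z, zb in zip(Z, zbar_i)))
    df = (g_n - 1, N - g_n)
    if within == 0.0:
        if between == 0.0:
            statistic, p = 0.0, 1.0
        else:
            statistic, p = float("inf"), 0.0
    else:
        statistic = (N - g_n) / (g_n - 1) * between / within
        p = float(stats.f.sf(statistic, *df))
    return LeveneResult(
        statistic=float(statistic),
        p_value=float(p),
        group_variances=np.array([np.var(g, ddof=1) for g in gs]),
        df=df,
        alpha=float(alpha),
        reject=bool(p < alpha),
    )


@dataclass
class ComparisonReport:
    """Reliability comparison across subjects sharing near-equal point predictions."""

    subjects: pd.DataFrame  # label, mean, median, pi_lower, pi_upper, pi_length
    joint: LeveneResult
    pairwise: pd.DataFrame  # label_1, label_2, statistic, p, p_bonferroni, reject
    alpha: float
    k: int

    def narrative(self) -> list[str]:
        """Plain-language pairwise reading: prefer the shorter interval when the
        variance test rejects and point predictions are close."""
        lines = []
        sub = self.subjects.set_index("label")
        scale = max(sub["pi_length"].max(), 1e-12)
        for _, row in self.pairwise.iterrows():
            a, b = row["label_1"], row["label_2"]
            close = abs(sub.loc[a, "mean"] - sub.loc[b, "mean"]) <= 0.25 * scale
            if row["reject"]:
                short = a if sub.loc[a, "pi_length"] <= sub.loc[b, "pi_length"] else b
                other = b if short == a else a
                qualifier = "near-equal point predictions; " if close else ""
                lines.append(
                    f"{a} vs {b}: variances differ (p={row['p']:.3g}); {qualifier}"
                    f"{short} has the shorter {100 * (1 - self.alpha):g}% PI "
                    f"({sub.loc[short, 'pi_length']:.3f} vs {sub.loc[other, 'pi_length']:.3f}) "
                    f"and offers the more stable response"
                )
            else:
                lines.append(
                    f"{a} vs {b}: no evidence of unequal response variability "
                    f"(p={row['p']:.3g})"
                )
        return lines

    def summary(self) -> str:
        lines = [
            "Reliability comparison (inverse-transform sampling + Levene test)",
            "=" * 68,
            f"k = {self.k} pseudo-responses per subject, alpha = {self.alpha:g}",
            "",
            self.subjects.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"Joint Levene test: W = {self.joint.statistic:.4f}, "
            f"p = {self.joint.p_value:.4g}, df = {self.joint.df}, "
            f"{'reject' if self.joint.reject else 'do not reject'} H0",
            "",
            "Pairwise tests:",
            self.pairwise.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
        ]
        lines += self.narrative()
        lines.append("=" * 68)
        return "\n".join(lines)


def compare_reliability(
    forests: Forest | Sequence[Forest],
    subjects: Sequence[tuple[np.ndarray, str]],
    k: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    centering: str = "mean",
    alpha_pi: float = 0.05,
) -> ComparisonReport:
    """Compare prediction reliability across subjects (or drugs).

    ``forests`` is either one forest shared by all subjects (one drug, many
    patients) or a sequence with one forest per subject (one patient, many
    drugs).  Each subject receives independent tau draws.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to compare")
    if isinstance(forests, Forest):
        forest_list = [forests] * len(subjects)
    else:
        forest_list = list(forests)
        if len(forest_list) != len(subjects):
            raise ValueError("need one forest per subject (or a single shared forest)")

    children = np.random.SeedSequence(seed).spawn(len(subjects))
    samples: list[ResponseSample] = []
    rows = []
    for (x, label), forest, child in zip(subjects, forest_list, children):
        x = np.asarray(x, dtype=float)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        s = sample_response(forest, x, k=k, seed=sub_seed, source=str(label))
        samples.append(s)
        w = forest_weights(forest, x)
        taus = [alpha_pi / 2, 0.5, 1 - alpha_pi / 2]
        q_lo, q_med, q_hi = weighted_quantiles(forest.y, w[None, :], taus)[0]
        rows.append(
            {
                "label": str(label),
                "mean": float(w @ forest.y),
                "median": float(q_med),
                "pi_lower": float(q_lo),
                "pi_upper": float(q_hi),
                "pi_length": float(q_hi - q_lo),
            }
        )
    subjects_df = pd.DataFrame(rows)

    joint = levene_test([s.values for s in samples], centering=centering, alpha=alpha)
    pair_rows = []
    n_pairs = len(samples) * (len(samples) - 1) // 2
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            res = levene_test(
                [samples[i].values, samples[j].values], centering=centering, alpha=alpha
            )
            pair_rows.append(
                {
                    "label_1": subjects_df["label"][i],
                    "label_2": subjects_df["label"][j],
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "p_bonferroni": min(1.0, res.p_value * n_pairs),
                    "reject": res.reject,
                }
            )
    return ComparisonReport(
        subjects=subjects_df,
        joint=joint,
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
        k=k,
    )
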