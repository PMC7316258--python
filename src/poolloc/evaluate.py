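"""Error metrics and results tables.

Localization error is summarized per axis (X, Y, Z, Euclidean) as the
median of the absolute deviations — called MAD in this field's usage,
*not* the robust statistic median(|x - median(x)|), hence the function
name `median_abs_error` — bounded by the 25th-75th percentile
interquartile range of the same absolute deviations.  Classification
accuracy carries a Wilson score confidence interval.  Distribution
comparisons (Anderson-Darling normality, Kruskal-Wallis, Dunn's post-hoc
on mean ranks) are evaluation commentary delegated to standard routines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ErrorSummary",
    "deviations",
    "median_abs_error",
    "mad_iqr",
    "accuracy_with_wilson",
    "error_summary_table",
    "compare_error_distributions",
]

AXES = ("Euclidean", "X", "Y", "Z")


@dataclass(frozen=True)
class ErrorSummary:
    axis: str
    mad: float              # median of absolute deviations, m
    iqr: tuple[float, float]
    n: int

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if not self.iqr[0] <= self.mad <= self.iqr[1]:
            raise ValueError("MAD must lie inside its IQR")


def deviations(predicted: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-snippet absolute deviations between predicted and true coords.

    Both frames need columns (id, x, y, z); rows are matched on `id` and
    an id mismatch is an error.  Returns a frame with columns
    (id, X, Y, Z, Euclidean).
    """
    for name, df in (("predicted", predicted), ("truth", truth)):
        if not {"id", "x", "y", "z"} <= set(df.columns):
            raise ValueError(f"{name} frame needs columns id, x, y, z")
    p = predicted.set_index("id").sort_index()
    t = truth.set_index("id").sort_index()
    if not p.index.equals(t.index):
        raise ValueError("predicted and truth snippet ids do not match")
    d = p[["x", "y", "z"]].to_numpy() - t[["x", "y", "z"]].to_numpy()
    out = pd.DataFrame({
        "id": p.index,
        "X": np.abs(d[:, 0]),
        "Y": np.abs(d[:, 1]),
        "Z": np.abs(d[:, 2]),
        "Euclidean": np.linalg.norm(d, axis=1),
    })
    return out.reset_index(drop=True)


def median_abs_error(abs_deviations, axis: str = "Euclidean") -> ErrorSummary:
    """MAD (median of absolute deviations) with 25th-75th pct IQR.

    Quantiles use linear interpolation between order statistics.
    """
    v = np.asarray(abs_deviations, dtype=float)
    if v.size == 0:
        raise ValueError("empty deviation set")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return ErrorSummary(axis, float(med), (float(q25), float(q75)), v.size)


#: Alias under the field's customary name.
mad_iqr = median_abs_error


def accuracy_with_wilson(
    predicted_ids, true_ids, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Percent accuracy with a Wilson score interval, both on the 0-100
    scale."""
    pred = np.asarray(predicted_ids)
    true = np.asarray(true_ids)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("need equal-length, non-empty id sequences")
    k = int(np.sum(pred == true))
    n = pred.size
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return 100.0 * k / n, (100.0 * lo, 100.0 * hi)


def error_summary_table(deviation_frames: dict[str, pd.DataFrame]
                        ) -> pd.DataFrame:
    """Stack {method: deviations frame} into a long summary table with one
    row per (method, axis): MAD, IQR bounds and n — nothing is reported
    without its uncertainty summary."""
    rows = []
    for method, frame in deviation_frames.items():
        for axis in AXES:
            s = median_abs_error(frame[axis].to_numpy(), axis)
            rows.append({
                "method": method, "axis": axis, "MAD": s.mad,
                "IQR_low": s.iqr[0], "IQR_high": s.iqr[1], "n": s.n,
            })
    return pd.DataFrame(rows)


def _dunn_posthoc(groups: dict[str, np.ndarray], alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Dunn's pairwise mean-rank z-tests with Bonferroni family
    correction (compact standard formulation with tie correction)."""
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    sizes = [len(groups[g]) for g in names]
    ranks = stats.rankdata(values)
    n = values.size
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    mean_ranks = {}
    start = 0
    for g, sz in zip(names, sizes):
        mean_ranks[g] = ranks[start:start + sz].mean()
        start += sz
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / na + 1 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"a": a, "b": b, "z": z, "p": p,
                     "p_adjusted": min(1.0, p * m),
                     "significant": p * m < alpha})
    return pd.DataFrame(rows)


def compare_error_distributions(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict:
    """Normality (Anderson-Darling) per group, Kruskal-Wallis across
    groups, and Dunn's post-hoc pairwise comparisons at a 5% family
    threshold."""
    if len(groups) < 2:
        raise ValueError("need >= 2 deviation sets to compare")
    ad = {
        g: stats.anderson(np.asarray(v, dtype=float), dist="norm")
        for g, v in groups.items()
    }
    kw_stat, kw_p = stats.kruskal(*[groups[g] for g in groups])
    return {
        "anderson_darling": ad,
        "kruskal_wallis": {"statistic": float(kw_stat), "p": float(kw_p)},
        "dunn": _dunn_posthoc(
            {g: np.asarray(v, dtype=float) for g, v in groups.items()},
            alpha,
        ),
    }
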