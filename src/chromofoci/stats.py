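"""Welch-family statistics and Tukey outlier flagging.

These are the tests used for group comparisons of per-cell imaging
measurements: the two-tailed Welch t test for two conditions, Welch's one-way
ANOVA (with the Brown-Forsythe F available as a companion statistic) for
three or more, the Games-Howell post-hoc for pairwise comparisons under
unequal variances, and Tukey's 1.5 x IQR rule for box-plot outliers.

All statistics are computed from the textbook formulas; scipy supplies only
the t, F and studentized-range distribution functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WelchTResult",
    "WelchAnovaResult",
    "OutlierFlags",
    "welch_t",
    "welch_anova",
    "brown_forsythe_f",
    "games_howell",
    "tukey_outliers",
    "boxplot_stats",
]


@dataclass
class WelchTResult:
    t: float
    df: float
    p: float


def _clean(sample, name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError(f"{name} must be 1-D with n >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def welch_t(x, y) -> WelchTResult:
    """Two-tailed unpaired t test with Welch's correction.

    t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y) with the
    Welch-Satterthwaite degrees of freedom; identical samples give t = 0,
    p = 1.
    """
    x = _clean(x, "x")
    y = _clean(y, "y")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    denom2 = vx / nx + vy / ny
    if denom2 == 0:
        raise ValueError("both samples have zero variance")
    t = (x.mean() - y.mean()) / np.sqrt(denom2)
    df = denom2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchTResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


@dataclass
class WelchAnovaResult:
    f_star: float
    df1: float
    df2: float
    p: float
    group_summaries: pd.DataFrame  # n, mean, variance per group


def _group_arrays(groups) -> list[np.ndarray]:
    if isinstance(groups, dict):
        groups = list(groups.values())
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.var(ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance")
    return arrays


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Weights w_i = n_i / s2_i; the statistic is the weighted between-group
    mean square over 1 + 2(k-2)/(k^2-1) * A, with
    A = sum (1 - w_i/W)^2 / (n_i - 1) and df2 = (k^2 - 1) / (3 A).
    """
    arrays = _group_arrays(groups)
    k = len(arrays)
    n = np.array([len(g) for g in arrays], dtype=float)
    mean = np.array([g.mean() for g in arrays])
    var = np.array([g.var(ddof=1) for g in arrays])
    w = n / var
    w_total = w.sum()
    grand = (w * mean).sum() / w_total
    a = (((1 - w / w_total) ** 2) / (n - 1)).sum()
    numerator = (w * (mean - grand) ** 2).sum() / (k - 1)
    f_star = numerator / (1 + 2 * (k - 2) / (k**2 - 1) * a)
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * a)
    p = float(sps.f.sf(f_star, df1, df2))
    summaries = pd.DataFrame({"n": n.astype(int), "mean": mean, "variance": var})
    return WelchAnovaResult(f_star=float(f_star), df1=df1, df2=float(df2), p=p,
                            group_summaries=summaries)


def brown_forsythe_f(groups) -> tuple[float, float, float, float]:
    """Brown-Forsythe's variance-robust F (companion statistic).

    F = sum n_i (mean_i - grand)^2 / sum (1 - n_i/N) s2_i, with
    Satterthwaite denominator degrees of freedom.  Returns (F, df1, df2, p).
    """
    arrays = _group_arrays(groups)
    k = len(arrays)
    n = np.array([len(g) for g in arrays], dtype=float)
    mean = np.array([g.mean() for g in arrays])
    var = np.array([g.var(ddof=1) for g in arrays])
    big_n = n.sum()
    grand = np.concatenate(arrays).mean()
    num = (n * (mean - grand) ** 2).sum()
    c = (1 - n / big_n) * var
    denom = c.sum()
    f = num / denom
    df1 = k - 1.0
    df2 = denom**2 / ((c**2 / (n - 1)).sum())
    return float(f), df1, float(df2), float(sps.f.sf(f, df1, df2))


def games_howell(groups, names: list[str] | None = None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons with unequal variances.

    For each pair, q = |mean difference| / sqrt((s2_i/n_i + s2_j/n_j) / 2)
    with per-pair Welch degrees of freedom; the adjusted p comes from the
    studentized range distribution with k = number of groups.
    """
    arrays = _group_arrays(groups)
    k = len(arrays)
    if names is None:
        if isinstance(groups, dict):
            names = list(groups.keys())
        else:
            names = [f"group{i}" for i in range(k)]
    n = np.array([len(g) for g in arrays], dtype=float)
    mean = np.array([g.mean() for g in arrays])
    var = np.array([g.var(ddof=1) for g in arrays])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            half_var = var[i] / n[i] + var[j] / n[j]
            se = np.sqrt(half_var / 2.0)
            diff = mean[i] - mean[j]
            df = half_var**2 / (
                (var[i] / n[i]) ** 2 / (n[i] - 1) + (var[j] / n[j]) ** 2 / (n[j] - 1)
            )
            q = abs(diff) / se
            p_adj = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
            rows.append(
                {
                    "group1": names[i], "group2": names[j],
                    "mean_diff": float(diff), "se": float(np.sqrt(half_var)),
                    "df": float(df), "q": float(q), "p_adj": p_adj,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OutlierFlags:
    flags: np.ndarray  # bool per value
    fences: tuple[float, float]
    quartiles: tuple[float, float]


def tukey_outliers(values) -> OutlierFlags:
    """Flag values strictly beyond the Tukey fences Q1 - 1.5 IQR, Q3 + 1.5 IQR.

    Quartiles use linear interpolation between order statistics; values
    exactly on a fence are not flagged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) < 4:
        raise ValueError("need a 1-D sample with n >= 4")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = (arr < lower) | (arr > upper)
    return OutlierFlags(flags=flags, fences=(float(lower), float(upper)),
                        quartiles=(float(q1), float(q3)))


def boxplot_stats(values) -> dict:
    """Box-plot summary: median, quartiles, Tukey whisker ends and outliers.

    Whiskers extend to the most extreme observations within 1.5 x IQR of the
    quartiles, matching the figure convention used with Tukey outliers.
    """
    arr = np.asarray(values, dtype=float)
    out = tukey_outliers(arr)
    inliers = arr[~out.flags]
    return {
        "median": float(np.median(arr)),
        "q1": out.quartiles[0],
        "q3": out.quartiles[1],
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": arr[out.flags].tolist(),
        "n": int(arr.size),
    }
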