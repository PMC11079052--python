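"""The phase-separation buffering diagnostic.

Liquid-liquid phase separation predicts *concentration buffering*: above a
saturation concentration c_sat, extra protein goes into growing condensates
while the concentration inside each focus stays pinned at c_sat.  The
alternative, *size buffering*, keeps foci size and number fixed while the
concentrations inside foci and in the nucleoplasm rise together with total
expression.  The diagnostic regresses focus concentration (log scale), summed
focus area and focus count against log total expression and calls the regime
from the three coefficients of determination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BufferingTestResult",
    "ExpressionBins",
    "loglog_r2",
    "run_buffering_test",
    "ratio_stability",
    "bin_expression",
]


def loglog_r2(x, y, log_y: bool = True) -> tuple[float, float, float, float]:
    """OLS of (optionally log10) y on log10 x; returns (r2, slope, slope_se, intercept).

    r2 is the squared Pearson correlation of the regressed variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.any(x <= 0):
        raise ValueError("x must be positive for the log scale")
    if log_y and np.any(y <= 0):
        raise ValueError("y must be positive when log_y is set")
    lx = np.log10(x)
    ly = np.log10(y) if log_y else y
    if np.ptp(lx) == 0:
        raise ValueError("expression range degenerate (zero variance in x)")
    if np.ptp(ly) == 0:  # constant response: r2 = 0 by convention, flat line
        return 0.0, 0.0, 0.0, float(ly[0])
    res = stats.linregress(lx, ly)
    return float(res.rvalue**2), float(res.slope), float(res.stderr), float(res.intercept)


@dataclass
class BufferingTestResult:
    """R-squared values of the three regressions and the regime call."""

    r2_concentration: float
    r2_area: float
    r2_count: float
    slope_concentration: float
    slope_concentration_se: float
    slope_area: float
    slope_area_se: float
    slope_count: float
    slope_count_se: float
    n_cells: int
    n_excluded_no_foci: int
    regime_call: Literal["concentration_buffering", "size_buffering", "indeterminate"]
    r2_high: float
    r2_low: float


def _call_regime(r2_conc: float, r2_area: float, r2_count: float,
                 r2_high: float, r2_low: float) -> str:
    if r2_conc <= r2_low and r2_area >= r2_high:
        return "concentration_buffering"
    if r2_conc >= r2_high and max(r2_area, r2_count) <= r2_low:
        return "size_buffering"
    return "indeterminate"


def run_buffering_test(records: pd.DataFrame, r2_high: float = 0.5, r2_low: float = 0.2,
                       ) -> BufferingTestResult:
    """Run the three regressions against log10 total expression and call the regime.

    ``records`` needs columns total_expression, foci_concentration,
    foci_area_um2, foci_count.  Cells without foci cannot contribute a focus
    concentration and are excluded (counted); focus concentration is regressed
    on the log scale, area and count untransformed.
    """
    required = ["total_expression", "foci_concentration", "foci_area_um2", "foci_count"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    with_foci = records[records["foci_count"] > 0]
    n_excluded = len(records) - len(with_foci)
    if len(with_foci) < 10:
        raise ValueError(
            f"need >= 10 cells with foci, got {len(with_foci)} "
            f"({n_excluded} excluded without foci)"
        )
    x = with_foci["total_expression"].to_numpy()
    r2_c, sl_c, se_c, _ = loglog_r2(x, with_foci["foci_concentration"].to_numpy(), log_y=True)
    r2_a, sl_a, se_a, _ = loglog_r2(x, with_foci["foci_area_um2"].to_numpy(), log_y=False)
    r2_n, sl_n, se_n, _ = loglog_r2(x, with_foci["foci_count"].to_numpy(), log_y=False)
    return BufferingTestResult(
        r2_concentration=r2_c, r2_area=r2_a, r2_count=r2_n,
        slope_concentration=sl_c, slope_concentration_se=se_c,
        slope_area=sl_a, slope_area_se=se_a,
        slope_count=sl_n, slope_count_se=se_n,
        n_cells=len(with_foci), n_excluded_no_foci=n_excluded,
        regime_call=_call_regime(r2_c, r2_a, r2_n, r2_high, r2_low),
        r2_high=r2_high, r2_low=r2_low,
    )


@dataclass
class RatioStability:
    """Regression of the foci/nucleoplasm ratio on log expression."""

    slope: float
    slope_se: float
    r2: float
    stable: bool
    slope_bound: float


def ratio_stability(records: pd.DataFrame, slope_bound: float = 0.1) -> RatioStability:
    """Regress the foci/nucleoplasm ratio on log10 expression; flag stability.

    A stable ratio (|slope| below ``slope_bound`` per decade of expression) is
    the signature of size buffering.
    """
    if "ratio_foci_nucleoplasm" in records.columns:
        ratio = records["ratio_foci_nucleoplasm"].to_numpy()
    else:
        ratio = (records["foci_concentration"] / records["nucleoplasm_concentration"]).to_numpy()
    x = records["total_expression"].to_numpy()
    if len(x) < 3:
        raise ValueError("need >= 3 cells")
    r2, slope, se, _ = loglog_r2(x, ratio, log_y=False)
    return RatioStability(slope=slope, slope_se=se, r2=r2,
                          stable=abs(slope) < slope_bound, slope_bound=slope_bound)


@dataclass
class ExpressionBins:
    """Low/medium/high expression terciles."""

    labels: tuple[str, ...]
    bins: dict[str, list]
    rule: str
    degenerate: bool = False


def bin_expression(records: pd.DataFrame, n_bins: int = 3,
                   id_col: str = "cell_id") -> ExpressionBins:
    """Split cells into expression terciles on log10 total expression.

    Bin sizes follow the largest-remainder rule (earlier bins get the extra
    cells); ties in expression are broken by stable cell-id order.  An
    all-equal expression column yields a single degenerate bin (flagged).
    """
    if len(records) < n_bins:
        raise ValueError(f"need at least {n_bins} cells")
    labels = ("low", "medium", "high")[:n_bins] if n_bins <= 3 else tuple(
        f"bin{i}" for i in range(n_bins))
    e = records["total_expression"].to_numpy(dtype=float)
    if np.any(e <= 0):
        raise ValueError("total_expression must be positive")
    ids = records[id_col].to_numpy()
    if np.ptp(e) == 0:
        return ExpressionBins(labels=labels[:1], bins={labels[0]: list(ids)},
                              rule="degenerate: all expressions equal", degenerate=True)
    order = np.lexsort((np.arange(len(e)), np.log10(e)))  # stable in input order
    n = len(e)
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    bins = {}
    start = 0
    for lab, size in zip(labels, sizes):
        bins[lab] = list(ids[order[start:start + size]])
        start += size
    return ExpressionBins(labels=labels, bins=bins,
                          rule=f"terciles of log10 expression, sizes {sizes}")
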