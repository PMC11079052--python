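"""FRAP normalization, two-phase association fitting, and recovery summaries.

The double normalization divides the bleached-spot signal by a non-bleached
control spot (correcting for acquisition photobleaching) and rescales by the
pre-bleach levels, so that 1 is the pre-bleach fluorescence:

    v(t) = (frap(t) - bg(t)) / (ctrl(t) - bg(t))
           * (ctrl_pre - bg_pre) / (frap_pre - bg_pre)

with *_pre the means over the pre-bleach frames.  Recovery is fitted with a
two-phase association model Y(t) = y0 + a(1 - e^(-k_f t)) + b(1 - e^(-k_s t));
the mobile fraction is the fitted curve at the last observed time point
(immobile = 100% - mobile) and T50 is the time at which the fitted curve
crosses 0.5, i.e. 50% of the pre-bleach level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import two_phase_curve

__all__ = [
    "FrapTrace",
    "NormalizedFrapTrace",
    "TwoPhaseFit",
    "FrapSummary",
    "normalize_frap",
    "fit_two_phase",
    "summarize_fit",
    "aggregate_traces",
    "read_frap_csv",
    "write_frap_csv",
]


@dataclass
class FrapTrace:
    """Raw FRAP acquisition: bleached spot, control spot and background.

    Frames 0..n_prebleach-1 precede the bleach; the frame at index
    ``n_prebleach`` is T0, the first post-bleach image.
    """

    time_s: np.ndarray
    frap_spot: np.ndarray
    control_spot: np.ndarray
    background: np.ndarray
    n_prebleach: int

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.frap_spot = np.asarray(self.frap_spot, dtype=float)
        self.control_spot = np.asarray(self.control_spot, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = len(self.time_s)
        if not (len(self.frap_spot) == len(self.control_spot) == len(self.background) == n):
            raise ValueError("all four arrays must have equal length")
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if n < self.n_prebleach + 10:
            raise ValueError("need at least 10 post-bleach frames")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")


@dataclass
class NormalizedFrapTrace:
    """Double-normalized post-bleach recovery curve (1 = pre-bleach level)."""

    time_rel_s: np.ndarray  # 0 at T0
    value: np.ndarray
    prebleach_means: tuple[float, float, float]  # (frap, control, background)
    prebleach_normalized_mean: float  # mean of the normalized pre-bleach frames


def normalize_frap(trace: FrapTrace) -> NormalizedFrapTrace:
    """Apply the double normalization; returns the post-bleach series re-zeroed at T0."""
    nb = trace.n_prebleach
    ctrl_minus_bg = trace.control_spot - trace.background
    bad = np.flatnonzero(ctrl_minus_bg == 0)
    if bad.size:
        raise ZeroDivisionError(
            f"control spot equals background at frame {bad[0]} (t={trace.time_s[bad[0]]} s)"
        )
    frap_pre = float(trace.frap_spot[:nb].mean())
    ctrl_pre = float(trace.control_spot[:nb].mean())
    bg_pre = float(trace.background[:nb].mean())
    if ctrl_pre - bg_pre == 0 or frap_pre - bg_pre == 0:
        raise ZeroDivisionError("pre-bleach denominator is zero")
    prefactor = (ctrl_pre - bg_pre) / (frap_pre - bg_pre)
    value_all = (trace.frap_spot - trace.background) / ctrl_minus_bg * prefactor
    if not np.all(np.isfinite(value_all)):
        frame = int(np.flatnonzero(~np.isfinite(value_all))[0])
        raise ValueError(f"non-finite normalized value at frame {frame}")
    t0 = trace.time_s[nb]
    return NormalizedFrapTrace(
        time_rel_s=trace.time_s[nb:] - t0,
        value=value_all[nb:],
        prebleach_means=(frap_pre, ctrl_pre, bg_pre),
        prebleach_normalized_mean=float(value_all[:nb].mean()),
    )


@dataclass
class TwoPhaseFit:
    """Least-squares fit of the two-phase association model (k_fast >= k_slow)."""

    y0: float
    span_fast: float
    k_fast: float
    span_slow: float
    k_slow: float
    rss: float
    converged: bool
    n_points: int
    t_max: float = np.inf
    message: str = ""

    def predict(self, t) -> np.ndarray:
        return two_phase_curve(np.asarray(t, dtype=float), self.y0, self.span_fast,
                               self.k_fast, self.span_slow, self.k_slow)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    y0 = float(y[0])
    plateau = float(np.mean(y[-10:]))
    total_span = max(plateau - y0, 1e-6)
    return np.array([y0, 0.7 * total_span, 0.1, 0.3 * total_span, 0.01])


def fit_two_phase(nt: NormalizedFrapTrace, *, max_restarts: int = 5) -> TwoPhaseFit:
    """Fit Y(t) = y0 + a(1-e^(-k_f t)) + b(1-e^(-k_s t)) with nonnegative spans/rates.

    Initialization: y0 = first post-bleach value, total span = mean of the
    last 10 points minus y0 split 70/30 fast/slow, k_fast = 0.1/s,
    k_slow = 0.01/s; up to ``max_restarts`` multiplicatively jittered restarts
    on failure.  k_fast >= k_slow is enforced by swapping after convergence.
    """
    t = np.asarray(nt.time_rel_s, dtype=float)
    y = np.asarray(nt.value, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach points")
    lower = np.array([-np.inf, 0.0, 0.0, 0.0, 0.0])
    upper = np.full(5, np.inf)
    p0 = _initial_guess(t, y)
    rng = np.random.default_rng(0)
    best = None
    message = ""
    for attempt in range(max_restarts + 1):
        guess = p0 if attempt == 0 else p0 * rng.uniform(0.3, 3.0, size=5)
        guess = np.clip(guess, lower + 1e-12, None)
        guess[0] = p0[0]
        try:
            popt, _ = curve_fit(
                two_phase_curve, t, y, p0=guess, bounds=(lower, upper), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # no convergence for this start
            message = str(exc)
            continue
        rss = float(np.sum((two_phase_curve(t, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        p = p0
        return TwoPhaseFit(
            y0=float(p[0]), span_fast=float(p[1]), k_fast=float(p[2]),
            span_slow=float(p[3]), k_slow=float(p[4]),
            rss=float(np.sum((two_phase_curve(t, *p0) - y) ** 2)),
            converged=False, n_points=len(t), t_max=float(t[-1]),
            message=f"optimizer failed after {max_restarts + 1} starts: {message}",
        )
    (y0, a, kf, b, ks), rss = best
    if kf < ks:  # identifiability convention
        a, b = b, a
        kf, ks = ks, kf
    return TwoPhaseFit(
        y0=float(y0), span_fast=float(a), k_fast=float(kf),
        span_slow=float(b), k_slow=float(ks), rss=rss,
        converged=True, n_points=len(t), t_max=float(t[-1]),
    )


@dataclass
class FrapSummary:
    """Mobile/immobile percentages and half-recovery time from a fitted curve."""

    mobile_pct: float
    immobile_pct: float
    t50_s: float | None
    t50_reached: bool


def summarize_fit(fit: TwoPhaseFit, t_end: float) -> FrapSummary:
    """Evaluate the fitted curve at ``t_end`` (mobile fraction) and locate T50.

    T50 is the smallest t in [0, t_end] with Y(t) = 0.5 — 50% of the
    pre-bleach level — found by bisection to 1e-6 relative tolerance; absent
    (flagged) when the curve never reaches 0.5 in the window.
    """
    if not fit.converged:
        raise ValueError("cannot summarize a non-converged fit")
    if t_end <= 0 or t_end > fit.t_max * (1 + 1e-9):
        raise ValueError("t_end must be positive and inside the fitted window")
    mobile = 100.0 * float(fit.predict(t_end))
    summary_kwargs = dict(mobile_pct=mobile, immobile_pct=100.0 - mobile)
    y_end = fit.predict(t_end)
    if fit.predict(0.0) >= 0.5:
        return FrapSummary(**summary_kwargs, t50_s=0.0, t50_reached=True)
    if y_end < 0.5:
        return FrapSummary(**summary_kwargs, t50_s=None, t50_reached=False)
    lo, hi = 0.0, float(t_end)
    # Y is non-decreasing (nonnegative spans and rates) so bisection applies
    while hi - lo > 1e-6 * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if fit.predict(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return FrapSummary(**summary_kwargs, t50_s=0.5 * (lo + hi), t50_reached=True)


def aggregate_traces(traces: list[NormalizedFrapTrace], *, time_atol: float = 1e-6,
                     ) -> pd.DataFrame:
    """Per-timepoint mean and SEM across traces sharing one acquisition grid.

    Returns a frame with columns time_rel_s, mean, sem, n; sem is NaN when a
    single trace is supplied.
    """
    if not traces:
        raise ValueError("no traces to aggregate")
    ref = traces[0].time_rel_s
    for i, tr in enumerate(traces[1:], start=1):
        if len(tr.time_rel_s) != len(ref) or np.max(np.abs(tr.time_rel_s - ref)) > time_atol:
            raise ValueError(f"trace {i} time grid deviates beyond {time_atol} s")
    values = np.stack([tr.value for tr in traces])
    n = values.shape[0]
    mean = values.mean(axis=0)
    sem = values.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(ref), np.nan)
    return pd.DataFrame({"time_rel_s": ref, "mean": mean, "sem": sem, "n": n})


def write_frap_csv(trace: FrapTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "frap_spot": trace.frap_spot,
            "control_spot": trace.control_spot,
            "background": trace.background,
        }
    ).to_csv(path, index=False)


def read_frap_csv(path, n_prebleach: int) -> FrapTrace:
    df = pd.read_csv(path)
    required = ["time_s", "frap_spot", "control_spot", "background"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return FrapTrace(
        time_s=df["time_s"].to_numpy(),
        frap_spot=df["frap_spot"].to_numpy(),
        control_spot=df["control_spot"].to_numpy(),
        background=df["background"].to_numpy(),
        n_prebleach=n_prebleach,
    )
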