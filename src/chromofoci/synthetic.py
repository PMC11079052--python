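"""Synthetic microscopy scenes, FRAP traces, cell populations and satellite arrays.

Every generator takes an explicit integer seed and is fully deterministic for
a fixed parameter set.  The generators provide known ground truth for the
downstream quantification stages: rendered nuclei with DNA-dense foci
(chromocenters) over a dimmer nucleoplasm, fluorescence-recovery time series
following a two-phase association model with acquisition photobleaching, cell
populations obeying either a concentration-buffering or a size-buffering
regime, and tandem satellite-repeat sequences with CpG methylation masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SceneParams",
    "GroundTruth",
    "PopulationParams",
    "FrapSimParams",
    "MethylatedSequence",
    "ScenePlacementError",
    "simulate_scene",
    "simulate_population",
    "simulate_frap_trace",
    "simulate_satellite_array",
    "two_phase_curve",
    "regime_params",
    "SLOW_REGIME",
    "FAST_REGIME",
]


class ScenePlacementError(RuntimeError):
    """Raised when nuclei cannot be placed disjointly in the field of view."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a rendered two-channel nucleus scene.

    The DNA channel shows nuclei at ``nucleoplasm_level`` with foci at
    ``dna_foci_to_nucleoplasm_contrast`` times that level; the reporter
    channel either co-enriches at foci (``colocalized``) or stays flat
    across the nucleus (``diffuse``).  Intensities are arbitrary units.
    """

    nucleus_count: int = 5
    nucleus_radius_px: float = 40.0
    foci_per_nucleus_mean: float = 6.0
    focus_radius_px: float = 6.0
    dna_foci_to_nucleoplasm_contrast: float = 3.0
    reporter_mode: Literal["colocalized", "diffuse"] = "colocalized"
    reporter_foci_ratio: float = 3.0
    noise_sd: float = 0.0
    pixel_size_um: float = 0.1
    seed: int = 0
    image_shape: tuple[int, int] | None = None
    foci_per_nucleus_exact: int | None = None  # overrides the Poisson draw
    nucleoplasm_level: float = 1.0
    reporter_level: float = 1.0
    smoothing_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.nucleus_count < 1:
            raise ValueError("nucleus_count must be >= 1")
        if self.nucleus_radius_px <= 0 or self.focus_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.focus_radius_px >= self.nucleus_radius_px:
            raise ValueError("focus_radius_px must be smaller than nucleus_radius_px")
        if self.dna_foci_to_nucleoplasm_contrast < 1:
            raise ValueError("contrast must be >= 1")
        if self.reporter_mode not in ("colocalized", "diffuse"):
            raise ValueError(f"unknown reporter_mode {self.reporter_mode!r}")
        if self.reporter_foci_ratio < 0 or self.noise_sd < 0:
            raise ValueError("reporter_foci_ratio and noise_sd must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.foci_per_nucleus_mean < 0:
            raise ValueError("foci_per_nucleus_mean must be >= 0")


@dataclass
class GroundTruth:
    """Label masks and true per-nucleus quantities behind a rendered scene."""

    nucleus_label_mask: np.ndarray  # int32, 0 = background, labels 1..n
    foci_mask: np.ndarray  # bool, subset of nucleus_label_mask > 0
    per_nucleus_params: pd.DataFrame  # one row per nucleus id


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_centers(params: SceneParams, rng: np.random.Generator,
                   shape: tuple[int, int]) -> list[tuple[float, float]]:
    r = params.nucleus_radius_px
    n = params.nucleus_count
    if params.image_shape is None:
        # jittered grid: cell size 4r guarantees disjoint nuclei
        ncols = math.ceil(math.sqrt(n))
        cell = 4.0 * r
        order = rng.permutation(ncols * ncols)[:n]
        centers = []
        for k in order:
            i, j = divmod(int(k), ncols)
            jitter = rng.uniform(-r / 2, r / 2, size=2)
            centers.append(((i + 0.5) * cell + jitter[0], (j + 0.5) * cell + jitter[1]))
        return centers
    centers = []
    max_tries = 1000 * n
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise ScenePlacementError(
                f"could not place {n} disjoint nuclei of radius {r} in {shape} "
                f"after {max_tries} tries"
            )
        tries += 1
        c = (rng.uniform(r + 1, shape[0] - r - 1), rng.uniform(r + 1, shape[1] - r - 1))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 >= (2 * r + 2) ** 2 for o in centers):
            centers.append(c)
    return centers


def simulate_scene(params: SceneParams) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render a two-channel scene and its ground truth.

    Returns a dict with float64 ``dna`` and ``reporter`` rasters plus a
    :class:`GroundTruth` carrying the nucleus label mask, foci mask and the
    noise-free per-nucleus means/areas actually drawn.
    """
    rng = np.random.default_rng(params.seed)
    r = params.nucleus_radius_px
    if params.image_shape is None:
        ncols = math.ceil(math.sqrt(params.nucleus_count))
        side = int(math.ceil(ncols * 4.0 * r))
        shape = (side, side)
    else:
        shape = tuple(params.image_shape)
        if shape[0] < 2 * r + 2 or shape[1] < 2 * r + 2:
            raise ScenePlacementError("image_shape too small for nucleus radius")
    centers = _place_centers(params, rng, shape)

    nucleus_mask = np.zeros(shape, dtype=np.int32)
    foci_mask = np.zeros(shape, dtype=bool)
    rows = []
    contrast = params.dna_foci_to_nucleoplasm_contrast
    for label, center in enumerate(centers, start=1):
        disc = _disc(shape, center, r)
        nucleus_mask[disc] = label
        n_foci_wanted = (
            params.foci_per_nucleus_exact
            if params.foci_per_nucleus_exact is not None
            else int(rng.poisson(params.foci_per_nucleus_mean))
        )
        placed: list[tuple[float, float]] = []
        fr = params.focus_radius_px
        max_offset = r - fr - 1.0
        for _ in range(n_foci_wanted):
            for _try in range(100):
                rho = max_offset * math.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * math.pi)
                fc = (center[0] + rho * math.cos(theta), center[1] + rho * math.sin(theta))
                if all((fc[0] - o[0]) ** 2 + (fc[1] - o[1]) ** 2 >= (2 * fr + 1) ** 2
                       for o in placed):
                    placed.append(fc)
                    break
        nucleus_foci = np.zeros(shape, dtype=bool)
        for fc in placed:
            nucleus_foci |= _disc(shape, fc, fr)
        nucleus_foci &= disc
        foci_mask |= nucleus_foci
        foci_area = int(nucleus_foci.sum())
        nucleus_area = int(disc.sum())
        rows.append(
            {
                "nucleus_id": label,
                "foci_count": len(placed),
                "nucleus_area_px": nucleus_area,
                "foci_area_px": foci_area,
                "dna_foci_mean": params.nucleoplasm_level * contrast if placed else np.nan,
                "dna_nucleoplasm_mean": params.nucleoplasm_level,
                "reporter_foci_mean": (
                    params.reporter_level * params.reporter_foci_ratio
                    if (placed and params.reporter_mode == "colocalized")
                    else (params.reporter_level if placed else np.nan)
                ),
                "reporter_nucleoplasm_mean": params.reporter_level,
            }
        )

    inside = nucleus_mask > 0
    dna = np.zeros(shape, dtype=float)
    dna[inside] = params.nucleoplasm_level
    dna[foci_mask] = params.nucleoplasm_level * contrast
    reporter = np.zeros(shape, dtype=float)
    reporter[inside] = params.reporter_level
    if params.reporter_mode == "colocalized":
        reporter[foci_mask] = params.reporter_level * params.reporter_foci_ratio

    if params.smoothing_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        dna = gaussian_filter(dna, params.smoothing_sigma_px)
        reporter = gaussian_filter(reporter, params.smoothing_sigma_px)
    if params.noise_sd > 0:
        dna = np.clip(dna + rng.normal(0, params.noise_sd, shape), 0, None)
        reporter = np.clip(reporter + rng.normal(0, params.noise_sd, shape), 0, None)

    truth = GroundTruth(
        nucleus_label_mask=nucleus_mask,
        foci_mask=foci_mask,
        per_nucleus_params=pd.DataFrame(rows).set_index("nucleus_id", drop=False),
    )
    return {"dna": dna, "reporter": reporter}, truth


# ---------------------------------------------------------------------------
# cell populations for the buffering test


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of a simulated cell population for the buffering diagnostic.

    ``concentration_buffering`` pins the focus concentration at ``c_sat``
    (condensates grow with expression); ``size_buffering`` keeps foci size and
    number fixed while concentrations inside and outside foci rise together
    with expression, so the foci/nucleoplasm ratio is stable.
    """

    regime: Literal["concentration_buffering", "size_buffering"]
    n_cells: int = 100
    c_sat: float = 100.0
    nucleoplasm_sat: float = 20.0
    expression_log10_range: tuple[float, float] = (-1.0, 1.0)
    foci_count_fixed: int = 15
    foci_area_um2_mid: float = 20.0
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("concentration_buffering", "size_buffering"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")
        if self.c_sat <= 0 or self.nucleoplasm_sat <= 0:
            raise ValueError("c_sat and nucleoplasm_sat must be positive")
        lo, hi = self.expression_log10_range
        if not hi > lo:
            raise ValueError("expression_log10_range must be non-degenerate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def simulate_population(params: PopulationParams) -> pd.DataFrame:
    """Simulate one cell per row under the requested buffering regime.

    Columns: cell_id, total_expression, foci_concentration, foci_area_um2,
    foci_count, nucleoplasm_concentration, ratio_foci_nucleoplasm.
    Total expression E is drawn log-uniform; concentrations are anchored so
    that a cell at the geometric-mean expression has focus concentration
    ``c_sat`` and nucleoplasm concentration ``nucleoplasm_sat``.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.expression_log10_range
    log10_e = rng.uniform(lo, hi, params.n_cells)
    e = 10.0**log10_e
    e_mid = 10.0 ** ((lo + hi) / 2)
    rel = e / e_mid

    noise = {
        name: _lognormal_noise(rng, params.noise_cv, params.n_cells)
        for name in ("conc", "nuc", "area", "count")
    }
    if params.regime == "concentration_buffering":
        foci_conc = params.c_sat * noise["conc"]
        nucleoplasm = params.nucleoplasm_sat * noise["nuc"]
        foci_area = params.foci_area_um2_mid * rel * noise["area"]
    else:  # size_buffering
        foci_conc = params.c_sat * rel * noise["conc"]
        nucleoplasm = params.nucleoplasm_sat * rel * noise["nuc"]
        foci_area = params.foci_area_um2_mid * noise["area"]
    foci_count = np.maximum(1, np.rint(params.foci_count_fixed * noise["count"])).astype(int)

    return pd.DataFrame(
        {
            "cell_id": np.arange(params.n_cells),
            "total_expression": e,
            "foci_concentration": foci_conc,
            "foci_area_um2": foci_area,
            "foci_count": foci_count,
            "nucleoplasm_concentration": nucleoplasm,
            "ratio_foci_nucleoplasm": foci_conc / nucleoplasm,
        }
    )


# ---------------------------------------------------------------------------
# FRAP traces


def two_phase_curve(t: np.ndarray, y0: float, span_fast: float, k_fast: float,
                    span_slow: float, k_slow: float) -> np.ndarray:
    """Two-phase association recovery Y(t) = y0 + Σ span·(1 − e^(−k·t))."""
    t = np.asarray(t, dtype=float)
    return (
        y0
        + span_fast * -np.expm1(-k_fast * t)
        + span_slow * -np.expm1(-k_slow * t)
    )


@dataclass(frozen=True)
class FrapSimParams:
    """Parameters of a simulated FRAP acquisition.

    The bleached spot recovers along a two-phase association curve (on the
    normalized scale, 1 = pre-bleach level); both the FRAP and the control
    spot decay as exp(-acquisition_bleach_rate * t) from imaging illumination;
    the background is constant.  Additive Gaussian noise on every channel.
    """

    y0: float = 0.1
    span_fast: float = 0.4
    k_fast: float = 0.1
    span_slow: float = 0.4
    k_slow: float = 0.01
    duration_s: float = 400.0
    interval_s: float = 1.0
    n_prebleach: int = 5
    acquisition_bleach_rate: float = 0.0
    background_level: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    amplitude: float = 1.0  # pre-bleach fluorescence of both spots (a.u.)

    def __post_init__(self) -> None:
        if self.k_fast < self.k_slow or self.k_slow < 0:
            raise ValueError("need k_fast >= k_slow >= 0")
        if self.span_fast < 0 or self.span_slow < 0:
            raise ValueError("spans must be >= 0")
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if self.duration_s <= 0 or self.interval_s <= 0:
            raise ValueError("duration_s and interval_s must be positive")
        if self.duration_s / self.interval_s < 10:
            raise ValueError("need at least 10 frames (duration / interval >= 10)")
        if self.acquisition_bleach_rate < 0 or self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("rates, background and noise must be >= 0")


def simulate_frap_trace(params: FrapSimParams):
    """Simulate a raw FRAP acquisition; returns a ``frap.FrapTrace``.

    Frame k is acquired at t = k * interval_s; frames 0..n_prebleach-1 are
    pre-bleach, frame n_prebleach is T0 (first post-bleach image).
    """
    from .frap import FrapTrace

    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration_s / params.interval_s))
    t = np.arange(n_frames) * params.interval_s
    t0 = params.n_prebleach * params.interval_s

    model = np.ones(n_frames)
    post = t >= t0
    model[post] = two_phase_curve(
        t[post] - t0, params.y0, params.span_fast, params.k_fast,
        params.span_slow, params.k_slow,
    )
    decay = np.exp(-params.acquisition_bleach_rate * t)
    frap_spot = params.amplitude * model * decay + params.background_level
    control_spot = params.amplitude * decay + params.background_level
    background = np.full(n_frames, params.background_level)
    if params.noise_sd > 0:
        frap_spot = frap_spot + rng.normal(0, params.noise_sd, n_frames)
        control_spot = control_spot + rng.normal(0, params.noise_sd, n_frames)
        background = background + rng.normal(0, params.noise_sd, n_frames)
    return FrapTrace(
        time_s=t,
        frap_spot=frap_spot,
        control_spot=control_spot,
        background=background,
        n_prebleach=params.n_prebleach,
    )


def regime_params(mobile_frac: float, t50_s: float, *, y0: float = 0.1,
                  k_fast: float, k_slow: float, t_end_s: float = 395.0,
                  **extra) -> FrapSimParams:
    """Solve for the spans of a two-phase curve with a given end-point mobile
    fraction and half-recovery time, at fixed y0 and rate constants.

    The constraints Y(t_end) = mobile_frac and Y(t50) = 0.5 are linear in
    (span_fast, span_slow), so the spans follow from a 2x2 system.
    """
    a = np.array(
        [
            [-np.expm1(-k_fast * t_end_s), -np.expm1(-k_slow * t_end_s)],
            [-np.expm1(-k_fast * t50_s), -np.expm1(-k_slow * t50_s)],
        ]
    )
    b = np.array([mobile_frac - y0, 0.5 - y0])
    span_fast, span_slow = np.linalg.solve(a, b)
    if span_fast < 0 or span_slow < 0:
        raise ValueError(
            f"no nonnegative spans reach mobile={mobile_frac}, t50={t50_s}"
            f" at k_fast={k_fast}, k_slow={k_slow}, y0={y0}"
        )
    return FrapSimParams(
        y0=y0, span_fast=float(span_fast), k_fast=k_fast,
        span_slow=float(span_slow), k_slow=k_slow, **extra,
    )


# Canonical regimes mirroring the Table-1 contrast between wild-type mouse
# ESCs (slow, partially immobile) and DNA-methylation-free cells (fast, almost
# fully mobile): mobile 75.2% with T50 75.5 s vs mobile 97.5% with T50 9.9 s.
SLOW_REGIME = regime_params(0.752, 75.5, k_fast=0.1, k_slow=0.01)
FAST_REGIME = regime_params(0.975, 9.9, k_fast=0.15, k_slow=0.02)


# ---------------------------------------------------------------------------
# satellite arrays


@dataclass
class MethylatedSequence:
    """A nucleotide sequence with a CpG methylation mask.

    ``methylated_cpg`` holds 0-based positions p of methylated cytosines with
    seq[p] == 'C' and seq[p+1] == 'G' (forward strand only).
    """

    seq: str
    methylated_cpg: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACGT")
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(f"non-ACGT character {self.seq[pos]!r} at position {pos}")
        self.methylated_cpg = frozenset(self.methylated_cpg)
        for p in self.methylated_cpg:
            if not (0 <= p < len(self.seq) - 1 and self.seq[p] == "C" and self.seq[p + 1] == "G"):
                raise ValueError(f"position {p} is not a CpG cytosine")

    def cpg_positions(self) -> list[int]:
        return [i for i in range(len(self.seq) - 1) if self.seq[i] == "C" and self.seq[i + 1] == "G"]


def simulate_satellite_array(unit_seq: str, n_copies: int, substitution_rate: float = 0.0,
                             cpg_methylation_prob: float = 1.0, seed: int = 0,
                             ) -> MethylatedSequence:
    """Tandem-repeat a unit, apply per-base substitutions, methylate CpGs.

    Emulates a pericentromeric major-satellite array: ``n_copies`` tandem
    copies of ``unit_seq`` with independent substitutions at
    ``substitution_rate`` per base, then each CpG cytosine (scored on the
    mutated sequence) methylated independently with ``cpg_methylation_prob``.
    """
    unit_seq = unit_seq.upper()
    if set(unit_seq) - set("ACGT"):
        raise ValueError("unit_seq must contain only A, C, G, T")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if not (0 <= substitution_rate <= 1 and 0 <= cpg_methylation_prob <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer((unit_seq * n_copies).encode(), dtype=np.uint8).copy()
    if substitution_rate > 0:
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        hit = rng.uniform(size=arr.size) < substitution_rate
        for i in np.flatnonzero(hit):
            choices = alphabet[alphabet != arr[i]]
            arr[i] = rng.choice(choices)
    seq = arr.tobytes().decode()
    cpg = [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]
    meth = [p for p in cpg if rng.uniform() < cpg_methylation_prob]
    return MethylatedSequence(seq=seq, methylated_cpg=frozenset(meth))
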