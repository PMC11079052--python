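"""Nucleus segmentation, chromocenter detection and per-nucleus measurements.

Nuclei are segmented from the DNA channel (global Otsu by default, or an
imported external mask); DNA-dense foci are then detected by thresholding
*within* each nucleus, which makes detection invariant to absolute nuclear
brightness.  Measurements follow the convention that the nucleoplasm is the
nucleus with the foci depleted, and the per-channel enrichment is the ratio
of mean intensity in foci over mean intensity in the nucleoplasm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "FociConfig",
    "NucleusMeasurement",
    "DistributionCall",
    "segment_nuclei",
    "detect_foci",
    "measure_nuclei",
    "classify_distribution",
    "summarize_calls",
    "measurements_to_frame",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Nucleus segmentation settings for the DNA channel."""

    method: Literal["threshold_otsu", "external_mask"] = "threshold_otsu"
    min_nucleus_area_um2: float = 20.0
    fill_holes: bool = True
    split_touching: bool = False
    projection: Literal["max", "none"] = "max"
    smoothing_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.min_nucleus_area_um2 <= 0:
            raise ValueError("min_nucleus_area_um2 must be positive")


@dataclass(frozen=True)
class FociConfig:
    """Per-nucleus foci detection settings."""

    threshold_rule: Literal["otsu_within_nucleus", "mean_plus_k_sd"] = "otsu_within_nucleus"
    k: float = 2.0
    min_focus_area_um2: float = 0.1
    smoothing_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_rule == "mean_plus_k_sd" and self.k <= 0:
            raise ValueError("k must be positive for mean_plus_k_sd")
        if self.min_focus_area_um2 < 0 or self.smoothing_sigma_px < 0:
            raise ValueError("min_focus_area_um2 and smoothing_sigma_px must be >= 0")


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop connected components with fewer than min_px pixels."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def _project(image: np.ndarray, projection: str) -> np.ndarray:
    if image.ndim == 2:
        return image
    if image.ndim == 3:
        if projection == "max":
            return image.max(axis=0)
        raise ValueError("3D input requires projection='max'")
    raise ValueError(f"expected 2D raster or 3D stack, got ndim={image.ndim}")


def segment_nuclei(dna_channel: np.ndarray, config: SegmentationConfig,
                   pixel_size_um: float = 1.0,
                   external_mask: np.ndarray | None = None) -> np.ndarray:
    """Segment nuclei from the DNA channel; returns an int32 label mask.

    Labels are contiguous from 1; objects below the minimum area are removed.
    With ``method='external_mask'`` the supplied mask is validated and
    relabeled rather than recomputed.  An image with no nuclei yields an
    all-zero mask (logged), never an exception.
    """
    if config.method == "external_mask":
        if external_mask is None:
            raise ValueError("external_mask method requires an external_mask array")
        if external_mask.shape != _project(dna_channel, config.projection).shape:
            raise ValueError("external mask shape does not match image")
        if np.any(external_mask < 0):
            raise ValueError("external mask must be nonnegative integer labels")
        mask = external_mask > 0
    else:
        img = _project(np.asarray(dna_channel, dtype=float), config.projection)
        if img.size == 0:
            raise ValueError("empty image")
        smoothed = gaussian(img, config.smoothing_sigma_px, preserve_range=True) \
            if config.smoothing_sigma_px > 0 else img
        if np.ptp(smoothed) == 0:
            logger.warning("constant image: no nuclei found")
            return np.zeros(smoothed.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
        mask = smoothed > thr
    min_px = max(1, int(round(config.min_nucleus_area_um2 / pixel_size_um**2)))

    def _clean(m: np.ndarray) -> np.ndarray:
        if config.fill_holes:
            m = ndimage.binary_fill_holes(m)
        return _remove_small(m, min_px)

    mask = _clean(mask)
    if config.method == "threshold_otsu" and not mask.any():
        # A DNA channel with bright chromocenters has a three-mode histogram
        # (background / nucleoplasm / foci) on which binary Otsu can lock
        # onto the foci mode, leaving no nucleus-sized object.  Fall back to
        # the lowest of the two three-class Otsu thresholds.
        try:
            thr = threshold_multiotsu(smoothed, classes=3)[0]
        except ValueError:
            thr = None
        if thr is not None:
            logger.info("binary Otsu left no nuclei; retrying with 3-class Otsu")
            mask = _clean(smoothed > thr)
    if config.split_touching and mask.any():
        distance = ndimage.distance_transform_edt(mask)
        markers = cc_label(distance > 0.5 * distance.max())
        labels = watershed(-distance, markers, mask=mask).astype(np.int32)
    else:
        labels = cc_label(mask).astype(np.int32)
    if labels.max() == 0:
        logger.warning("no nuclei found after filtering")
    return labels


def detect_foci(dna_channel: np.ndarray, nucleus_mask: np.ndarray, config: FociConfig,
                pixel_size_um: float = 1.0) -> np.ndarray:
    """Detect DNA-dense foci with a threshold computed independently per nucleus.

    Returns a boolean mask that is a subset of ``nucleus_mask > 0``.  A
    nucleus with constant intensity contributes no foci (threshold undefined).
    """
    img = np.asarray(dna_channel, dtype=float)
    if img.shape != nucleus_mask.shape:
        raise ValueError("image and nucleus mask shapes differ")
    if config.smoothing_sigma_px > 0:
        img = gaussian(img, config.smoothing_sigma_px, preserve_range=True)
    foci = np.zeros(img.shape, dtype=bool)
    min_px = max(1, int(round(config.min_focus_area_um2 / pixel_size_um**2)))
    for lab in np.unique(nucleus_mask):
        if lab == 0:
            continue
        sel = nucleus_mask == lab
        vals = img[sel]
        if np.ptp(vals) == 0:
            logger.info("nucleus %d has constant intensity: no foci", lab)
            continue
        if config.threshold_rule == "otsu_within_nucleus":
            thr = threshold_otsu(vals)
        else:
            thr = vals.mean() + config.k * vals.std()
        nucleus_foci = sel & (img > thr)
        nucleus_foci = _remove_small(nucleus_foci, min_px)
        foci |= nucleus_foci
    return foci


@dataclass
class NucleusMeasurement:
    """Areas, foci count and per-channel intensity measurements of one nucleus.

    ``ratios`` (mean in foci / mean in nucleoplasm) are present only when the
    nucleus has at least one focus.
    """

    nucleus_id: int
    nucleus_area_um2: float
    foci_count: int
    foci_area_um2: float
    mean_foci: dict[str, float] = field(default_factory=dict)
    mean_nucleoplasm: dict[str, float] = field(default_factory=dict)
    total_nuclear: dict[str, float] = field(default_factory=dict)
    ratio: dict[str, float] = field(default_factory=dict)
    nucleus_area_px: int = 0
    foci_area_px: int = 0


def measure_nuclei(channels: dict[str, np.ndarray], nucleus_mask: np.ndarray,
                   foci_mask: np.ndarray, pixel_size_um: float,
                   ) -> list[NucleusMeasurement]:
    """Measure per-channel foci/nucleoplasm intensities and areas per nucleus.

    Areas are converted to um^2 with ``pixel_size_um**2``; intensities stay in
    input units.  The integrated nuclear signal decomposes exactly as
    total = mean_foci * foci_area + mean_nucleoplasm * nucleoplasm_area
    (areas in pixels).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    foci_mask = np.asarray(foci_mask, dtype=bool)
    if np.any(foci_mask & (nucleus_mask == 0)):
        raise ValueError("foci mask contains pixels outside every nucleus")
    px_area = pixel_size_um**2
    out = []
    for lab in np.unique(nucleus_mask):
        if lab == 0:
            continue
        nucleus = nucleus_mask == lab
        foci = nucleus & foci_mask
        nucleoplasm = nucleus & ~foci_mask
        n_px = int(nucleus.sum())
        f_px = int(foci.sum())
        n_foci = int(cc_label(foci).max())
        m = NucleusMeasurement(
            nucleus_id=int(lab),
            nucleus_area_um2=n_px * px_area,
            foci_count=n_foci,
            foci_area_um2=f_px * px_area,
            nucleus_area_px=n_px,
            foci_area_px=f_px,
        )
        for name, img in channels.items():
            img = np.asarray(img, dtype=float)
            mean_foci = float(img[foci].mean()) if f_px else np.nan
            mean_nucleo = float(img[nucleoplasm].mean()) if n_px > f_px else np.nan
            m.mean_foci[name] = mean_foci
            m.mean_nucleoplasm[name] = mean_nucleo
            m.total_nuclear[name] = float(img[nucleus].sum())
            if n_foci > 0 and np.isfinite(mean_nucleo) and mean_nucleo != 0:
                m.ratio[name] = mean_foci / mean_nucleo
        out.append(m)
    return out


def measurements_to_frame(measurements: list[NucleusMeasurement]) -> pd.DataFrame:
    """Flatten measurements to one tidy row per nucleus."""
    rows = []
    for m in measurements:
        row = {
            "nucleus_id": m.nucleus_id,
            "nucleus_area_um2": m.nucleus_area_um2,
            "foci_count": m.foci_count,
            "foci_area_um2": m.foci_area_um2,
        }
        for ch in m.mean_foci:
            row[f"mean_foci_{ch}"] = m.mean_foci[ch]
            row[f"mean_nucleoplasm_{ch}"] = m.mean_nucleoplasm[ch]
            row[f"total_nuclear_{ch}"] = m.total_nuclear[ch]
            row[f"ratio_{ch}"] = m.ratio.get(ch, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DistributionCall:
    """Spotty / mixed / diffuse classification of one nucleus."""

    label: Literal["spotty", "mixed", "diffuse"]
    ratio_used: float | None
    thresholds: tuple[float, float]  # (t_spotty, t_diffuse)


def classify_distribution(m: NucleusMeasurement, channel: str,
                          thresholds: tuple[float, float] = (1.5, 1.1),
                          ) -> DistributionCall:
    """Classify a nucleus as spotty, mixed or diffuse from its enrichment ratio.

    Diffuse when there are no foci or the ratio is at or below ``t_diffuse``;
    spotty at or above ``t_spotty``; mixed in between.
    """
    t_spotty, t_diffuse = thresholds
    if not t_spotty > t_diffuse >= 1:
        raise ValueError("need t_spotty > t_diffuse >= 1")
    if m.foci_count == 0 or channel not in m.ratio:
        return DistributionCall("diffuse", None, thresholds)
    ratio = m.ratio[channel]
    if ratio <= t_diffuse:
        lab = "diffuse"
    elif ratio >= t_spotty:
        lab = "spotty"
    else:
        lab = "mixed"
    return DistributionCall(lab, ratio, thresholds)


CATEGORIES = ("spotty", "mixed", "diffuse")


def summarize_calls(calls: pd.DataFrame, group_col: str = "group",
                    replicate_col: str = "replicate", label_col: str = "label",
                    ) -> pd.DataFrame:
    """Per-group category fractions as mean +/- SD across replicates.

    ``calls`` has one row per cell.  Fractions within each replicate sum to 1;
    with a single replicate the SD is reported as NaN (flagged by n_replicates).
    """
    if calls.empty:
        raise ValueError("no calls to summarize")
    rows = []
    for group, gdf in calls.groupby(group_col, sort=True):
        per_rep = []
        for _, rdf in gdf.groupby(replicate_col, sort=True):
            counts = rdf[label_col].value_counts()
            total = len(rdf)
            per_rep.append([counts.get(c, 0) / total for c in CATEGORIES])
        fr = np.array(per_rep)
        n_rep = fr.shape[0]
        row = {"group": group, "n_replicates": n_rep, "n_cells": len(gdf)}
        for i, c in enumerate(CATEGORIES):
            row[f"{c}_mean"] = fr[:, i].mean()
            row[f"{c}_sd"] = fr[:, i].std(ddof=1) if n_rep > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
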