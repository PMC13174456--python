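"""Immunofluorescence marker quantification.

Three markers, three readouts:

* **ITGB4** (integrin beta-4, basal keratinocyte adhesion): mean fluorescence
  intensity within a manually annotated basal-epidermis ROI.
* **Ki67** (proliferation): positive-nucleus counts normalized per unit
  epidermal length and per rete ridge.
* **CD31** (PECAM-1, endothelium): intensity-thresholded object segmentation
  in the papillary dermis, per-object geometric/intensity morphometrics
  (area, eccentricity, solidity, perimeter, axes, aspect ratio, sum/mean/
  median intensity) and per-sample summaries over five annotated regions,
  including the CD31-positive area fraction (microvascular density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from dermatomics.morphometrics import AGG_STATS, aggregate_stats

#: objects smaller than this (px) are treated as speckle and dropped
MIN_OBJECT_PX = 5

VESSEL_PROPERTIES = (
    "area", "eccentricity", "solidity", "perimeter",
    "major_axis", "minor_axis", "aspect_ratio",
    "sum_intensity", "mean_intensity", "median_intensity",
)


class CompartmentError(ValueError):
    """Operation applied to an ROI of the wrong anatomical compartment."""


@dataclass
class AnnotatedRegion:
    image: np.ndarray  # single-channel intensity raster
    roi_mask: np.ndarray
    compartment: str  # "basal-epidermis" | "epidermis" | "papillary-dermis"
    sample_id: str = ""
    region_index: int = 1

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError("AnnotatedRegion image must be single-channel")
        if not self.roi_mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class VesselObject:
    object_id: int
    area: float
    eccentricity: float
    solidity: float
    perimeter: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    sum_intensity: float
    mean_intensity: float
    median_intensity: float


@dataclass
class VesselFeatureSummary:
    """Per-sample summary: property stats averaged across regions."""

    stats: dict[str, float] = field(default_factory=dict)
    cd31_area_fraction: float = np.nan
    n_regions: int = 0


def itgb4_mean_intensity(region: AnnotatedRegion) -> float:
    """Mean raw intensity within the basal-epidermis ROI."""
    if region.compartment != "basal-epidermis":
        raise CompartmentError(
            f"ITGB4 quantification needs a basal-epidermis ROI, "
            f"got {region.compartment!r}"
        )
    return float(region.image[region.roi_mask.astype(bool)].mean())


def ki67_indices(
    n_positive_cells: int,
    epidermal_length_px: float,
    n_ridge_cells: int = 0,
    ridge_count: int = 0,
) -> tuple[float, float]:
    """Proliferation indices: cells per epidermal length and cells per ridge.

    The per-ridge index is undefined (NaN) when there are no ridges; the
    per-length index is still emitted.
    """
    if n_positive_cells < 0 or n_ridge_cells < 0 or ridge_count < 0:
        raise ValueError("cell and ridge counts must be non-negative")
    if epidermal_length_px <= 0:
        raise ValueError("epidermal_length_px must be positive")
    per_length = n_positive_cells / epidermal_length_px
    per_ridge = n_ridge_cells / ridge_count if ridge_count > 0 else np.nan
    return per_length, per_ridge


def segment_cd31(
    region: AnnotatedRegion,
    threshold: float | str = "otsu",
    min_object_px: int = MIN_OBJECT_PX,
) -> np.ndarray:
    """Threshold CD31 signal inside the ROI and label 8-connected objects.

    ``threshold`` is an absolute intensity, or ``"otsu"`` to resolve it from
    the ROI pixel histogram. Objects below ``min_object_px`` are dropped.
    Returns the labeled object raster (0 = background).
    """
    if region.compartment != "papillary-dermis":
        raise CompartmentError(
            f"CD31 segmentation needs a papillary-dermis ROI, "
            f"got {region.compartment!r}"
        )
    roi = region.roi_mask.astype(bool)
    if threshold == "otsu":
        vals = region.image[roi]
        if np.ptp(vals) == 0:
            return np.zeros(region.image.shape, int)
        threshold = threshold_otsu(vals)
    binary = (region.image >= threshold) & roi
    labels, n = ndimage.label(binary, structure=np.ones((3, 3)))
    if n:
        areas = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(areas < min_object_px) + 1
        labels[np.isin(labels, small)] = 0
        labels, _ = ndimage.label(labels > 0, structure=np.ones((3, 3)))
    return labels


def vessel_features(labels: np.ndarray, image: np.ndarray) -> list[VesselObject]:
    """Geometric and intensity morphometrics for each labeled object.

    Axes and eccentricity come from the ellipse of inertia, solidity from the
    convex hull (area / convex area). Degenerate objects (zero minor axis)
    get unit axes/solidity rather than NaN.
    """
    out: list[VesselObject] = []
    for rp in regionprops(labels, intensity_image=image):
        major = float(rp.axis_major_length)
        minor = float(rp.axis_minor_length)
        solidity = float(rp.solidity)
        if minor <= 0 or major <= 0:  # 1-px or collinear object
            major = max(major, 1.0)
            minor = 1.0
            solidity = 1.0
        pix = rp.image_intensity[rp.image]
        out.append(
            VesselObject(
                object_id=int(rp.label),
                area=float(rp.area),
                eccentricity=float(rp.eccentricity),
                solidity=solidity,
                perimeter=float(rp.perimeter),
                major_axis=major,
                minor_axis=minor,
                aspect_ratio=major / minor,
                sum_intensity=float(pix.sum()),
                mean_intensity=float(pix.mean()),
                median_intensity=float(np.median(pix)),
            )
        )
    return out


def _region_stats(objects: list[VesselObject]) -> dict[str, float]:
    stats: dict[str, float] = {}
    for prop in VESSEL_PROPERTIES:
        vals = np.array([getattr(o, prop) for o in objects], float)
        for stat, val in aggregate_stats(vals).items():
            stats[f"{prop}_{stat}"] = val
    return stats


def summarize_cd31(
    objects_per_region: list[list[VesselObject]],
    cd31_areas: list[float],
    roi_areas: list[float],
    pooled: bool = False,
) -> VesselFeatureSummary:
    """Summarize CD31 objects across the annotated regions of one sample.

    Default behavior computes per-region distribution statistics and averages
    them across regions (``pooled=True`` instead pools all objects before
    computing statistics). The area fraction is the mean of per-region
    CD31-positive area / ROI area.
    """
    if not objects_per_region:
        raise ValueError("need at least one region")
    fractions = [c / r for c, r in zip(cd31_areas, roi_areas)]
    if pooled:
        stats = _region_stats([o for reg in objects_per_region for o in reg])
    else:
        per_region = [_region_stats(reg) for reg in objects_per_region]
        keys = per_region[0].keys()
        stats = {
            k: float(np.nanmean([r[k] for r in per_region])) for k in keys
        }
    return VesselFeatureSummary(
        stats=stats,
        cd31_area_fraction=float(np.mean(fractions)),
        n_regions=len(objects_per_region),
    )


def summary_to_row(summary: VesselFeatureSummary, sample_id: str) -> dict:
    return {
        "ID": sample_id,
        "cd31_area_fraction": summary.cd31_area_fraction,
        **{f"cd31_{k}": v for k, v in summary.stats.items()},
    }
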