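"""Whole-slide image reading, tissue detection, and slice extraction.

Pyramidal TIFF/SVS files are read with :mod:`tifffile`; flat RGB images
(PNG/TIFF) are accepted as single-level pyramids so the same code path works
on pre-cropped slices. Tissue is detected at a downsampled working resolution
(~16x) by combining Otsu thresholds on the HSV hue channel and on the
per-pixel channel minimum; each connected tissue component becomes a
:class:`SliceRegion` cropped at level-1 resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: components smaller than this (in working-resolution pixels) are not tissue
MIN_COMPONENT_PX = 50_000

#: default working downsample factor relative to level 0
WORKING_FACTOR = 16.0


class FormatError(ValueError):
    """Raised when an input image does not satisfy the RGB contract."""


@dataclass
class PyramidImage:
    """An ordered pyramid of RGB rasters, level 0 = full resolution."""

    levels: list[np.ndarray]
    factors: list[float]
    path: str = ""

    def __post_init__(self) -> None:
        for lvl in self.levels:
            if lvl.ndim != 3 or lvl.shape[2] != 3:
                raise FormatError(
                    f"every pyramid level must be RGB; got shape {lvl.shape}"
                )
        heights = [lvl.shape[0] for lvl in self.levels]
        if any(h2 > h1 for h1, h2 in zip(heights, heights[1:])):
            raise FormatError("pyramid level dimensions must be non-increasing")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class TissueMask:
    """Binary tissue mask at the working (downsampled) resolution."""

    mask: np.ndarray
    working_factor: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return int(ndimage.label(self.mask, structure=np.ones((3, 3)))[1])


@dataclass
class SliceRegion:
    """One tissue slice: a level-1 crop with its mask and provenance boxes.

    Bounding boxes are row-major, 0-based, half-open ``(row0, col0, row1, col1)``.
    """

    slice_id: int
    bbox_downsampled: tuple[int, int, int, int]
    bbox_level1: tuple[int, int, int, int]
    image: np.ndarray
    mask: np.ndarray
    component_area: int


def load_pyramid(path: str | Path) -> PyramidImage:
    """Read a pyramidal TIFF/SVS or a flat RGB image as a :class:`PyramidImage`.

    Per-level downsample factors are computed from the dimension ratio against
    level 0. A flat image yields a single level with factor 1.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    levels: list[np.ndarray]
    if suffix in {".tif", ".tiff", ".svs"}:
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            levels = [np.asarray(lv.asarray()) for lv in series.levels]
    else:
        import imageio.v3 as iio

        levels = [np.asarray(iio.imread(str(path)))]
    # drop alpha if present, reject non-RGB
    for i, lvl in enumerate(levels):
        if lvl.ndim == 3 and lvl.shape[2] == 4:
            levels[i] = lvl[..., :3]
        elif lvl.ndim != 3 or lvl.shape[2] != 3:
            raise FormatError(
                f"expected 3-channel RGB, got "
                f"{lvl.shape[2] if lvl.ndim == 3 else 1} channel(s) in {path}"
            )
    h0 = levels[0].shape[0]
    factors = [h0 / lvl.shape[0] for lvl in levels]
    return PyramidImage(levels=levels, factors=factors, path=str(path))


def working_image(pyr: PyramidImage, target_factor: float = WORKING_FACTOR) -> np.ndarray:
    """Return an RGB raster at an effective downsample of ``target_factor``.

    An exact pyramid level (factor matches within 1%) is returned verbatim;
    otherwise the closest larger level (largest factor strictly below the
    target) is resampled down with order-1 interpolation.
    """
    if target_factor < 1:
        raise ValueError("target_factor must be >= 1")
    for lvl, f in zip(pyr.levels, pyr.factors):
        if abs(f - target_factor) / target_factor < 0.01:
            return lvl
    # closest larger pyramidal level: largest factor strictly below target
    candidates = [(f, i) for i, f in enumerate(pyr.factors) if f < target_factor]
    f_src, idx = max(candidates)
    src = pyr.levels[idx]
    zoom = f_src / target_factor
    out = ndimage.zoom(src.astype(np.float32), (zoom, zoom, 1), order=1)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def detect_tissue(
    working: np.ndarray,
    min_component_px: int = MIN_COMPONENT_PX,
    working_factor: float = WORKING_FACTOR,
) -> TissueMask:
    """Detect tissue on the working-resolution raster.

    Two Otsu-thresholded masks — one from the HSV hue channel, one from the
    per-pixel minimum across RGB channels — are combined by logical AND, then
    dilated (3x3, 2 iterations), hole-filled, and cleaned of components below
    ``min_component_px``.

    The hue-Otsu polarity is not fixed a priori: the side of the threshold
    whose mask better overlaps the non-white (low channel-minimum) pixels is
    taken as tissue, and the choice is recorded in the mask provenance.
    """
    if working.ndim != 3 or working.shape[2] != 3:
        raise FormatError("detect_tissue expects an RGB raster")
    img = working.astype(np.float64) / 255.0
    hue = rgb2hsv(img)[..., 0]
    chan_min = img.min(axis=2)
    provenance: dict = {"min_component_px": int(min_component_px)}
    if np.ptp(chan_min) == 0 or np.ptp(hue) == 0:  # Otsu undefined
        warnings.warn("constant-valued image; returning empty tissue mask")
        return TissueMask(
            np.zeros(working.shape[:2], bool), working_factor, provenance
        )
    t_min = threshold_otsu(chan_min)
    t_hue = threshold_otsu(hue)
    dark = chan_min < t_min  # tissue absorbs light -> low channel minimum
    hue_hi = hue > t_hue
    # polarity: pick the hue side that overlaps the dark pixels more
    if (hue_hi & dark).sum() >= ((~hue_hi) & dark).sum():
        hue_mask = hue_hi
        provenance["hue_polarity"] = "above"
    else:
        hue_mask = ~hue_hi
        provenance["hue_polarity"] = "below"
    mask = hue_mask & dark
    mask = ndimage.binary_dilation(mask, np.ones((3, 3), bool), iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n:
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_component_px) + 1
        mask = np.isin(labels, keep)
    return TissueMask(mask, working_factor, provenance)


def extract_slices(pyr: PyramidImage, tissue: TissueMask) -> list[SliceRegion]:
    """Crop one :class:`SliceRegion` per 8-connected tissue component.

    Working-resolution bounding boxes are mapped to level-1 coordinates
    (level 0 for a flat image) by the ratio of level dimensions, clamped to
    image bounds; slices are ordered by label index.
    """
    labels, n = ndimage.label(tissue.mask, structure=np.ones((3, 3)))
    if n == 0:
        return []
    lvl_idx = 1 if pyr.n_levels > 1 else 0
    target = pyr.levels[lvl_idx]
    scale_r = target.shape[0] / tissue.mask.shape[0]
    scale_c = target.shape[1] / tissue.mask.shape[1]
    out: list[SliceRegion] = []
    for sid, slc in enumerate(ndimage.find_objects(labels), start=1):
        if slc is None:  # pragma: no cover
            continue
        r0, r1 = slc[0].start, slc[0].stop
        c0, c1 = slc[1].start, slc[1].stop
        comp = labels[slc] == sid
        R0 = max(0, int(np.floor(r0 * scale_r)))
        C0 = max(0, int(np.floor(c0 * scale_c)))
        R1 = min(target.shape[0], int(np.ceil(r1 * scale_r)))
        C1 = min(target.shape[1], int(np.ceil(c1 * scale_c)))
        crop = target[R0:R1, C0:C1]
        mask_hi = ndimage.zoom(
            comp.astype(np.uint8),
            ((R1 - R0) / comp.shape[0], (C1 - C0) / comp.shape[1]),
            order=0,
        ).astype(bool)
        # guard off-by-one from zoom rounding
        mask_hi = mask_hi[: crop.shape[0], : crop.shape[1]]
        if mask_hi.shape != crop.shape[:2]:  # pragma: no cover
            pad = [(0, crop.shape[i] - mask_hi.shape[i]) for i in range(2)]
            mask_hi = np.pad(mask_hi, pad)
        out.append(
            SliceRegion(
                slice_id=sid,
                bbox_downsampled=(r0, c0, r1, c1),
                bbox_level1=(R0, C0, R1, C1),
                image=crop,
                mask=mask_hi,
                component_area=int(comp.sum()),
            )
        )
    return out
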