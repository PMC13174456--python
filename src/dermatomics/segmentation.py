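"""Epidermis segmentation: color filtering, stain separation, refinement.

The segmentation proceeds in three stages. First, a battery of empirical
color thresholds in LAB/HSV space removes background and non-epidermal
tissue (:func:`smooth_and_filter`). Second, the surviving pixels are
deconvolved into optical-density (OD) stain channels with a PCA-based
(Macenko-style) stain model, and the hematoxylin channel is turned into a
nuclear density mask (:func:`fit_stain_model`, :func:`nuclear_density_mask`).
Third, morphological refinement converts nuclear density into the final
epidermis mask (:func:`refine_epidermis`): the epidermis is the compartment
whose nuclei are dense enough that the local nuclear-mask mean exceeds 1/2.

Color encodings. The literal thresholds (L<50, L>200, A<150, H<110, S<40)
presume 8-bit channel encodings: L is rescaled from [0,100] to [0,255],
A and B are offset by +128, hue spans [0,179] (degrees/2) and S,V span
[0,255]. Conversions are done with scikit-image and rescaled accordingly;
an alternative 0-255 hue encoding is selectable via ``hue_range_255``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv, rgb2lab
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: canonical published H&E optical-density stain vectors (RGB order)
HEMATOXYLIN_OD = np.array([0.65, 0.70, 0.29])
EOSIN_OD = np.array([0.07, 0.99, 0.11])

#: per-site upper lightness threshold (8-bit L); pixels with L above are masked
SITE_L_HIGH = {"abdomen": 140, "graft": 160, "buttock": 200}


class ConfigError(ValueError):
    pass


class DegenerateStainError(RuntimeError):
    """The OD cloud has no resolvable two-stain structure."""


@dataclass(frozen=True)
class ColorFilterConfig:
    """Empirical color-threshold battery removing background and dermis.

    A pixel is *excluded* when any condition holds: L < ``l_low``;
    L > ``l_high`` (site-dependent); L < 100 and A < 150; H < ``h_max``;
    S < ``s_min``; R = G = B (pure gray). All on 8-bit encodings.
    """

    smoothing_sigma: float = 2.0
    l_low: int = 50
    l_high: int = 200  # buttock default; see SITE_L_HIGH
    la_pair: tuple[int, int] = (100, 150)
    h_max: int = 110
    s_min: int = 40
    hue_range_255: bool = False
    site: str = "buttock"

    @classmethod
    def for_site(cls, site: str, **overrides) -> "ColorFilterConfig":
        if site not in SITE_L_HIGH and "l_high" not in overrides:
            raise ConfigError(
                f"unknown site {site!r}; expected one of {sorted(SITE_L_HIGH)} "
                "or an explicit l_high override"
            )
        l_high = overrides.pop("l_high", SITE_L_HIGH.get(site))
        return cls(l_high=l_high, site=site, **overrides)


@dataclass(frozen=True)
class StainModel:
    """Two unit stain vectors in OD space, hematoxylin-like first."""

    od_matrix: np.ndarray  # (2, 3), rows unit-norm, non-negative
    background_intensity: float = 255.0

    def __post_init__(self) -> None:
        m = np.asarray(self.od_matrix, float)
        if m.shape != (2, 3):
            raise ValueError("od_matrix must be 2x3")
        if not np.allclose(np.linalg.norm(m, axis=1), 1, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.od_matrix[0]

    @property
    def eosin(self) -> np.ndarray:
        return self.od_matrix[1]


def canonical_stain_model() -> StainModel:
    """Fixed literature H&E stain vectors, used as a degenerate-fit fallback."""
    m = np.stack(
        [HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD),
         EOSIN_OD / np.linalg.norm(EOSIN_OD)]
    )
    return StainModel(m)


@dataclass
class EpidermisMask:
    """Final binary epidermis mask with labeled components ("trees")."""

    mask: np.ndarray
    labels: np.ndarray
    n_components: int
    provenance: dict = field(default_factory=dict)

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _lab_8bit(img01: np.ndarray) -> np.ndarray:
    lab = rgb2lab(img01)
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * 255.0 / 100.0
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return out


def _hsv_8bit(img01: np.ndarray, hue_range_255: bool) -> np.ndarray:
    hsv = rgb2hsv(img01)
    out = np.empty_like(hsv)
    out[..., 0] = hsv[..., 0] * (255.0 if hue_range_255 else 179.0)
    out[..., 1] = hsv[..., 1] * 255.0
    out[..., 2] = hsv[..., 2] * 255.0
    return out


def smooth_and_filter(image: np.ndarray, cfg: ColorFilterConfig) -> np.ndarray:
    """Gaussian-smooth each RGB channel and apply the exclusion battery.

    Returns the boolean *keep* mask (pixels surviving every condition).
    """
    img = image.astype(np.float64)
    if cfg.smoothing_sigma > 0:
        img = np.stack(
            [ndimage.gaussian_filter(img[..., c], cfg.smoothing_sigma)
             for c in range(3)],
            axis=-1,
        )
    img = np.clip(img, 0, 255)
    img01 = img / 255.0
    lab = _lab_8bit(img01)
    hsv = _hsv_8bit(img01, cfg.hue_range_255)
    L, A = lab[..., 0], lab[..., 1]
    H, S = hsv[..., 0], hsv[..., 1]
    rgb8 = np.round(img).astype(np.int32)
    exclude = (
        (L < cfg.l_low)
        | (L > cfg.l_high)
        | ((L < cfg.la_pair[0]) & (A < cfg.la_pair[1]))
        | (H < cfg.h_max)
        | (S < cfg.s_min)
        | ((rgb8[..., 0] == rgb8[..., 1]) & (rgb8[..., 1] == rgb8[..., 2]))
    )
    return ~exclude


def fit_stain_model(
    image: np.ndarray,
    keep: np.ndarray,
    *,
    od_transparency_floor: float = 0.15,
    angle_percentiles: tuple[float, float] = (1.0, 99.0),
    min_pixels: int = 1000,
    background: float = 255.0,
    fallback_on_degenerate: bool = False,
) -> StainModel:
    """Fit a two-stain OD model to the kept pixels (Macenko construction).

    Kept pixels are converted to optical density, transparent pixels (all-OD
    below the floor) are dropped, the principal 2-D OD plane is found by PCA,
    and the two extreme directions at the stated projection-angle percentiles
    become the stain vectors. The hematoxylin-like vector (largest red-channel
    OD: hematoxylin looks blue because it absorbs red) is ordered first.
    """
    pix = image[keep].astype(np.float64)
    od = -np.log((pix + 1.0) / background)
    od = od[(od > od_transparency_floor).any(axis=1)]
    if od.shape[0] < min_pixels:
        raise DegenerateStainError(
            f"only {od.shape[0]} usable OD pixels (need >= {min_pixels})"
        )
    # principal plane through the origin: stain mixtures are non-negative
    # combinations of the stain vectors, so the plane is NOT mean-centered
    cov = od.T @ od / od.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] < 1e-6 * max(evals[-1], 1e-12):
        if fallback_on_degenerate:
            logger.warning("degenerate OD cloud; falling back to canonical H&E vectors")
            return canonical_stain_model()
        raise DegenerateStainError("OD cloud is effectively rank-1 (single stain)")
    plane = evecs[:, -2:]  # columns: 2nd and 1st principal directions
    # orient the dominant axis so projections are positive
    if np.median(od @ plane[:, 1]) < 0:
        plane[:, 1] = -plane[:, 1]
    proj = od @ plane
    phi = np.arctan2(proj[:, 0], proj[:, 1])
    lo, hi = np.percentile(phi, angle_percentiles)
    v1 = plane @ np.array([np.sin(lo), np.cos(lo)])
    v2 = plane @ np.array([np.sin(hi), np.cos(hi)])
    vecs = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0, None)
        vecs.append(v / np.linalg.norm(v))
    # hematoxylin-like first: larger red-channel OD
    vecs.sort(key=lambda v: -v[0])
    return StainModel(np.stack(vecs), background)


def nuclear_density_mask(
    image: np.ndarray,
    keep: np.ndarray,
    stains: StainModel,
    od_floor: float = 0.2,
    gaussian_sigma: float = 2.0,
) -> np.ndarray:
    """Project OD onto the hematoxylin vector and threshold into nuclei.

    Values below ``od_floor`` are zeroed, the result is Gaussian-filtered and
    Otsu-thresholded. The output is always a subset of the keep-mask.
    """
    od = -np.log((image.astype(np.float64) + 1.0) / stains.background_intensity)
    h_conc = od @ stains.hematoxylin
    h_conc[~keep] = 0.0
    h_conc[h_conc < od_floor] = 0.0
    if not h_conc.any():
        warnings.warn("no hematoxylin signal above OD floor; empty nuclear mask")
        return np.zeros(keep.shape, bool)
    smoothed = ndimage.gaussian_filter(h_conc, gaussian_sigma)
    t = threshold_otsu(smoothed)
    return (smoothed > t) & keep


def _remove_small_objects(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_px) + 1
    return np.isin(labels, keep)


def refine_epidermis(
    nuclear: np.ndarray,
    *,
    min_object_px: int = 64,
    tissue_mask: np.ndarray | None = None,
    provenance: dict | None = None,
) -> EpidermisMask:
    """Morphological refinement of the nuclear density mask.

    Order: opening, small-object removal, opening x4 iterations, 10x10
    uniform (box-mean) filter, strict local-mean > 0.5 threshold, 8-connected
    component labeling. Structuring element is the 3x3 square throughout.
    """
    se = np.ones((3, 3), bool)
    m = ndimage.binary_opening(nuclear.astype(bool), se)
    m = _remove_small_objects(m, min_object_px)
    m = ndimage.binary_opening(m, se, iterations=4)
    local_mean = ndimage.uniform_filter(m.astype(np.float64), size=10)
    m = local_mean > 0.5
    if tissue_mask is not None:
        m &= tissue_mask.astype(bool)
    labels, n = ndimage.label(m, structure=np.ones((3, 3)))
    return EpidermisMask(m, labels, int(n), provenance or {})


def segment_epidermis(
    image: np.ndarray,
    cfg: ColorFilterConfig | None = None,
    *,
    tissue_mask: np.ndarray | None = None,
    od_floor: float = 0.2,
    min_object_px: int = 64,
    stain_fallback: bool = True,
) -> EpidermisMask:
    """Full segmentation: color filter -> stain model -> nuclei -> refinement."""
    cfg = cfg or ColorFilterConfig()
    keep = smooth_and_filter(image, cfg)
    if tissue_mask is not None:
        keep &= tissue_mask.astype(bool)
    try:
        stains = fit_stain_model(image, keep, fallback_on_degenerate=stain_fallback)
    except DegenerateStainError:
        if not stain_fallback:
            raise
        stains = canonical_stain_model()
    nuclear = nuclear_density_mask(image, keep, stains, od_floor=od_floor)
    prov = {
        "site": cfg.site,
        "l_high": cfg.l_high,
        "od_floor": od_floor,
        "stain_od_matrix": stains.od_matrix.tolist(),
    }
    return refine_epidermis(
        nuclear, min_object_px=min_object_px, tissue_mask=tissue_mask,
        provenance=prov,
    )
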