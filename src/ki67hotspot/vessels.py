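"""Brown-stained vessel-wall detection and elimination.

Vessel walls stain with DAB like immunopositive nuclei, so they must be
removed before cell extraction.  Two complementary detectors run on the Y
(CMYK) plane, where brown structures contrast best:

* an LBP-texture branch: edge-code density times Y intensity, mean
  filtered, thresholded and cleaned with morphology;
* a CORF-style contour branch: collinear difference-of-Gaussians
  sub-fields combined by a weighted geometric mean per orientation, with
  the maximum over orientations as the contour response.

Both binary maps are combined by union and small connected components are
dropped.  Each branch additionally keeps only elongated components
(perimeter^2 / 4*pi*area gate), so blob-like nuclei clusters are not
mistaken for walls; thin faint walls remain a known hard case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, remove_small_objects

from .errors import ConfigError, ShapeError
from .masks import MaskRole, RegionMask
from .texture import lbp_code_image
from .tissue import otsu_threshold

#: Smallest vessel-wall object of interest: area of a 15-px-diameter disk.
DEFAULT_MIN_OBJECT_PX = int(np.pi * 7.5**2)
#: Absolute floors under the data-driven thresholds, on the [0, 1] response scales.
LBP_WALLNESS_FLOOR = 0.18
CORF_RESPONSE_FLOOR = 0.02
#: Elongation gate: keep components with perimeter^2/(4 pi area) >= this.
ELONGATION_MIN = 2.0


@dataclass
class CorfConfig:
    n_orientations: int = 8
    sigma: float = 2.0
    n_subfields: int = 5
    subfield_spacing: float = 2.0
    threshold_quantile: float = 0.95

    def validate(self) -> None:
        if self.n_orientations < 4:
            raise ConfigError("n_orientations must be >= 4")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.n_subfields < 1 or self.subfield_spacing <= 0:
            raise ConfigError("invalid sub-field layout")
        if not 0 < self.threshold_quantile < 1:
            raise ConfigError("threshold_quantile must be in (0, 1)")


def corf_response(plane: np.ndarray, config: CorfConfig | None = None) -> np.ndarray:
    """Contour response: max over orientations of the weighted geometric
    mean of collinear, half-wave-rectified on-center DoG sub-fields.

    Zero on constant input and invariant to adding a constant to the plane
    (the DoG removes any offset).
    """
    config = config or CorfConfig()
    config.validate()
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ShapeError("corf_response expects a single-channel plane")
    dog = ndi.gaussian_filter(plane, 0.5 * config.sigma) - ndi.gaussian_filter(
        plane, config.sigma
    )
    rect = np.clip(dog, 0.0, None)
    eps = 1e-12
    log_rect = np.log(rect + eps)

    n_sub = config.n_subfields
    centers = (np.arange(n_sub) - (n_sub - 1) / 2.0) * config.subfield_spacing
    sigma_w = max(config.subfield_spacing * n_sub / 3.0, 1e-9)
    weights = np.exp(-(centers**2) / (2 * sigma_w**2))
    weights /= weights.sum()

    best = np.full_like(plane, -np.inf)  # log-space accumulator
    for k in range(config.n_orientations):
        theta = np.pi * k / config.n_orientations
        acc = np.zeros_like(plane)
        for w, c in zip(weights, centers):
            shift = (c * np.sin(theta), c * np.cos(theta))  # (dy, dx) along orientation
            acc += w * ndi.shift(log_rect, shift, order=1, mode="nearest")
        np.maximum(best, acc, out=best)
    return np.clip(np.exp(best) - eps, 0.0, None)


def _elongated_only(mask: np.ndarray, min_ratio: float = ELONGATION_MIN) -> np.ndarray:
    out = np.zeros_like(mask)
    lab = label(mask, connectivity=2)
    for rp in regionprops(lab):
        if rp.area < 4:
            continue
        ratio = rp.perimeter**2 / (4 * np.pi * rp.area) if rp.area else 0.0
        if ratio >= min_ratio:
            out[lab == rp.label] = True
    return out


def vessels_from_lbp(
    y_plane: np.ndarray,
    tissue_mask: np.ndarray,
    n_points: int = 8,
    sampling_radius: float = 2.0,
    mean_filter_size: int = 5,
) -> np.ndarray:
    """LBP branch: wall-likeness map -> mean filter -> threshold -> morphology.

    Wall-likeness is the Y intensity gated by edge-like LBP codes (uniform
    rotation-invariant codes with an intermediate number of set bits, i.e.
    contrast boundaries rather than flat regions).
    """
    y_plane = np.asarray(y_plane, dtype=np.float64)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if y_plane.shape != tissue_mask.shape:
        raise ShapeError("Y plane and tissue mask misaligned")
    if not tissue_mask.any():
        return np.zeros_like(tissue_mask)
    codes, _ = lbp_code_image(y_plane, n_points, sampling_radius, "uniform_rotation_invariant")
    edge = (codes >= 2) & (codes <= n_points - 2)
    wallness = ndi.uniform_filter(y_plane * edge, size=mean_filter_size)
    vals = wallness[tissue_mask]
    if vals.min() == vals.max():
        return np.zeros_like(tissue_mask)
    thr = max(otsu_threshold(vals), LBP_WALLNESS_FLOOR)
    mask = (wallness > thr) & tissue_mask
    mask = closing(mask, disk(2))
    mask = _elongated_only(mask)
    return mask & tissue_mask


def vessels_from_corf(
    y_plane: np.ndarray,
    tissue_mask: np.ndarray,
    config: CorfConfig | None = None,
) -> np.ndarray:
    """CORF branch: contour response -> quantile threshold -> morphology."""
    config = config or CorfConfig()
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        return np.zeros_like(tissue_mask)
    resp = corf_response(y_plane, config)
    thr = max(
        float(np.quantile(resp[tissue_mask], config.threshold_quantile)),
        CORF_RESPONSE_FLOOR,
    )
    mask = (resp > thr) & tissue_mask
    mask = closing(mask, disk(2))
    mask = _elongated_only(mask)
    return mask & tissue_mask


def vessel_map(
    lbp_mask: np.ndarray,
    corf_mask: np.ndarray,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
) -> RegionMask:
    """Union of the two detector masks with small components removed.

    Commutative in its two arguments; removing small objects is idempotent
    and anti-extensive (output is a subset of the union).
    """
    lbp_mask = np.asarray(lbp_mask, dtype=bool)
    corf_mask = np.asarray(corf_mask, dtype=bool)
    if lbp_mask.shape != corf_mask.shape:
        raise ShapeError("vessel masks misaligned")
    union = lbp_mask | corf_mask
    cleaned = remove_small_objects(union, max_size=max(int(min_object_px) - 1, 0), connectivity=2)
    return RegionMask(cleaned, MaskRole.VESSEL)
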