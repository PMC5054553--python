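"""Specimen (tissue) map construction.

The specimen map is built from the working-resolution image: black pixels
(R = G = B = 0) are non-scanned regions and excluded outright; the
remaining pixels are thresholded on the B - R difference image with Otsu's
method, then cleaned with morphological closing (disk of 5-8 px), hole
filling and removal of small structures.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, erosion, remove_small_objects

from .errors import ConfigError, ValidationError
from .masks import MaskRole, RegionMask
from .slide_io import SlideImage, fov_geometry

#: Default closing structuring-element radius (allowed range 5-8 px).
DEFAULT_DISK_RADIUS = 6
#: Fraction of one FOV's area below which holes/structures are removed.
SMALL_STRUCTURE_FOV_FRACTION = 1.0 / 50.0


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance over an ``n_bins`` histogram.

    Returns the upper edge of the last below-threshold bin, so values are
    split as ``value > threshold``.  Raises on constant input (no threshold
    exists).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValidationError("otsu_threshold needs at least 2 values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValidationError("otsu_threshold undefined for constant input")
    hist, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    p = hist.astype(np.float64) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        between = np.where(
            (w0 > 0) & (w1 > 0),
            (mu_total * w0 - mu) ** 2 / (w0 * w1),
            -np.inf,
        )
    # cut index t assigns bins [0..t] to the low class; threshold at the
    # upper edge of bin t (first-maximum tie break)
    t = int(np.argmax(between[:-1]))
    return float(edges[t + 1])


def morphological_cleanup(
    mask: np.ndarray, disk_radius: int, min_area: int
) -> np.ndarray:
    """Closing with ``disk(disk_radius)``, hole filling, small-object removal.

    Idempotent: applying it twice equals applying it once.
    """
    if not 5 <= disk_radius <= 8:
        raise ConfigError(f"disk_radius must be in [5, 8], got {disk_radius}")
    selem = disk(disk_radius)
    out = erosion(dilation(mask, selem), selem)
    out = ndi.binary_fill_holes(out)
    out = remove_small_objects(out, max_size=max(int(min_area) - 1, 0))
    return out


def build_specimen_map(
    image: SlideImage | np.ndarray,
    disk_radius: int = DEFAULT_DISK_RADIUS,
    min_area: int | None = None,
) -> RegionMask:
    """Build the tissue mask for a working-resolution RGB image.

    ``min_area`` defaults to one FOV's area at the image resolution divided
    by 50 -- large enough to close nuclei-scale holes, small enough that
    genuine gaps between tissue lobes survive.
    """
    if isinstance(image, SlideImage):
        pixels = image.pixels
        level = image.level
        if min_area is None:
            min_area = int(fov_geometry(image.um_per_px).area_px * SMALL_STRUCTURE_FOV_FRACTION)
    else:
        pixels = np.asarray(image)
        level = 0
        if min_area is None:
            min_area = 64
    rgb = pixels.astype(np.int64)
    non_black = ~np.all(rgb == 0, axis=-1)
    if not non_black.any():
        return RegionMask(np.zeros(rgb.shape[:2], bool), MaskRole.TISSUE, level=level)

    diff = rgb[..., 2] - rgb[..., 0]  # B - R
    vals = diff[non_black]
    if vals.min() == vals.max():
        warnings.warn("B - R difference is constant; returning empty tissue mask")
        return RegionMask(np.zeros(rgb.shape[:2], bool), MaskRole.TISSUE, level=level)
    thr = otsu_threshold(vals)
    mask = non_black & (diff > thr)
    mask = morphological_cleanup(mask, disk_radius, min_area)
    mask &= non_black
    return RegionMask(mask, MaskRole.TISSUE, level=level, meta={"otsu_threshold": thr})
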