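"""Color-artifact elimination and immunopositive-cell extraction.

At eight-fold reduced resolution a nucleus is only a few blurred pixels,
so per-nucleus morphometry is impossible and global thresholds are
unstable across slides.  Cells are instead found with the extended
regional minima (h-minima) transform on luminance: depressions shallower
than h -- background texture and pale immunonegative nuclei, i.e. the
non-immunoreactive region -- are filled by the reconstruction and end up
on the background side of the cut-off plane, while each DAB-dark well
deeper than h survives as one connected component that is reduced to its
centroid.  Choosing h between the luminance depth of pale hematoxylin
nuclei and dark DAB nuclei is what separates the two populations; larger h
extracts fewer, stronger cells.

Before extraction the lowest 5% of in-region luminance is clipped, which
immunizes the transform against small near-black color artifacts that
would otherwise stretch the luminance range of a field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima, reconstruction

from .errors import ConfigError, ValidationError

#: Percentage of lowest luminance values clipped in every processed region.
ARTIFACT_CUTOFF_PERCENT = 5.0
#: Gap (L units) between the 5th percentile and the minimum beyond which a
#: genuine color artifact is flagged.
ARTIFACT_GAP_L = 10.0
#: Default h on the 0-100 luminance scale: immunonegative (pale blue)
#: nuclei must stay on the background side of the cut-off plane.
DEFAULT_H = 20.0
#: Default h for the immunonegative pass on the hematoxylin-dominant plane.
DEFAULT_H_NEG = 8.0


@dataclass
class CellMarkerMap:
    """Centroids of extracted cell markers at working resolution."""

    centroids: np.ndarray  # (n, 2) as (x, y)
    h_value: float
    plane_id: str = ""
    artifact_flag: bool = False
    cell_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def count(self) -> int:
        return len(self.centroids)


def color_artifact_cutoff(
    lum: np.ndarray,
    region_mask: np.ndarray,
    percent: float = ARTIFACT_CUTOFF_PERCENT,
    gap_threshold: float = ARTIFACT_GAP_L,
) -> tuple[np.ndarray, bool]:
    """Clip the lowest ``percent`` of in-region luminance to that percentile.

    Returns the adjusted plane and an artifact flag that is set when the
    cut removed a luminance gap larger than ``gap_threshold`` (i.e. the
    minimum lay far below the percentile -- the signature of a small
    near-black artifact rather than ordinary dark nuclei).
    """
    lum = np.asarray(lum, dtype=np.float64)
    region_mask = np.asarray(region_mask, dtype=bool)
    if lum.shape != region_mask.shape:
        raise ValidationError("luminance and region mask misaligned")
    if not region_mask.any():
        raise ValidationError("empty region: nothing to cut")
    vals = lum[region_mask]
    p = float(np.percentile(vals, percent))
    flag = (p - float(vals.min())) > gap_threshold
    adjusted = lum.copy()
    sel = region_mask & (lum < p)
    adjusted[sel] = p
    return adjusted, flag


def extended_minima(plane: np.ndarray, mask: np.ndarray, h: float) -> np.ndarray:
    """Extended regional minima of depth >= ``h`` restricted to ``mask``.

    The h-minima reconstruction (erosion reconstruction of ``plane + h``
    under ``plane``) fills every depression shallower than ``h`` -- noise
    dips and pale immunonegative nuclei vanish -- and the regional minima
    of the result are the wells at least ``h`` deep.  Minima separated by a
    barrier rising less than ``h`` above their floors merge into one
    component, which is exactly the behaviour that avoids over-segmented
    cell areas.  Pixels outside ``mask`` are set brighter than everything
    inside so no minimum leaks across the mask boundary.

    Degenerate case: when no well of depth ``h`` exists the reconstruction
    is flat and every pixel is formally a regional minimum; that covers the
    whole mask and is reported as "no extrema" (an all-False mask).
    """
    if h <= 0:
        raise ConfigError("h must be positive")
    plane = np.asarray(plane, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if plane.shape != mask.shape:
        raise ValidationError("plane and mask misaligned")
    if not mask.any():
        return np.zeros_like(mask)
    fill = plane[mask].max() + 2.0 * h
    f = np.where(mask, plane, fill)
    rec = reconstruction(f + h, f, method="erosion")
    minima = local_minima(rec, connectivity=2, allow_borders=True) & mask
    if minima.sum() == mask.sum():
        return np.zeros_like(mask)
    return minima


def background_region(plane: np.ndarray, mask: np.ndarray, h: float) -> np.ndarray:
    """The non-immunoreactive side: in-mask complement of the extended
    minima (background plus immunonegative nuclei); by construction it
    partitions the mask together with the cell region."""
    return np.asarray(mask, bool) & ~extended_minima(plane, mask, h)


def _round_half_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 ties broken toward smaller values."""
    return np.ceil(np.asarray(x) - 0.5).astype(np.int64)


def extract_positive_cells(
    lum: np.ndarray,
    tumour_mask: np.ndarray,
    h: float = DEFAULT_H,
    plane_id: str = "L",
    artifact_flag: bool = False,
) -> CellMarkerMap:
    """Immunopositive-cell markers from the (artifact-clipped) luminance plane.

    Immunopositive nuclei are the luminance wells deeper than ``h``; the
    non-immunoreactive region (background and pale immunonegative nuclei)
    stays on the other side of the cut-off plane.  Each connected component
    (8-connectivity) of the cell region emits its center of mass rounded to
    the nearest pixel (ties toward smaller coordinates).  The marker count
    is non-increasing in ``h``.
    """
    cell_region = extended_minima(lum, tumour_mask, h)
    lab, n = ndi.label(cell_region, structure=np.ones((3, 3), int))
    if n == 0:
        centroids = np.empty((0, 2), dtype=np.int64)
    else:
        coms = np.asarray(ndi.center_of_mass(cell_region, lab, np.arange(1, n + 1)))
        ys = _round_half_down(coms[:, 0])
        xs = _round_half_down(coms[:, 1])
        centroids = np.stack([xs, ys], axis=1)
    return CellMarkerMap(
        centroids=centroids,
        h_value=float(h),
        plane_id=plane_id,
        artifact_flag=artifact_flag,
        cell_mask=cell_region,
    )


def extract_negative_cells(
    hema_plane: np.ndarray,
    tumour_mask: np.ndarray,
    h: float = DEFAULT_H_NEG,
    exclude_mask: np.ndarray | None = None,
) -> CellMarkerMap:
    """Immunonegative-cell markers: the same transform on a
    hematoxylin-dominant plane.

    Components overlapping ``exclude_mask`` (typically the already-found
    immunopositive cell region) are dropped so no nucleus is counted twice.
    """
    markers = extract_positive_cells(hema_plane, tumour_mask, h, plane_id="hematoxylin")
    if exclude_mask is not None and markers.count:
        exclude_mask = np.asarray(exclude_mask, bool)
        lab, n = ndi.label(markers.cell_mask, structure=np.ones((3, 3), int))
        overlapping = np.unique(lab[exclude_mask & (lab > 0)])
        keep_region = markers.cell_mask & ~np.isin(lab, overlapping)
        return extract_from_region(keep_region, h, "hematoxylin")
    return markers


def extract_from_region(cell_region: np.ndarray, h: float, plane_id: str) -> CellMarkerMap:
    """Centroids of an already-computed binary cell region."""
    lab, n = ndi.label(cell_region, structure=np.ones((3, 3), int))
    if n == 0:
        centroids = np.empty((0, 2), dtype=np.int64)
    else:
        coms = np.asarray(ndi.center_of_mass(cell_region, lab, np.arange(1, n + 1)))
        centroids = np.stack(
            [_round_half_down(coms[:, 1]), _round_half_down(coms[:, 0])], axis=1
        )
    return CellMarkerMap(centroids=centroids, h_value=float(h), plane_id=plane_id,
                         cell_mask=np.asarray(cell_region, bool))


def ki67_index(pos_count: int, neg_count: int) -> float:
    """Ki-67 proliferation index in percent: 100 * pos / (pos + neg)."""
    if pos_count < 0 or neg_count < 0:
        raise ValidationError("counts must be non-negative")
    total = pos_count + neg_count
    if total == 0:
        raise ValidationError("ki67_index undefined for zero total count")
    return 100.0 * pos_count / total
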