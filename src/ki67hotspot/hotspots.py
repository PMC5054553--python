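"""Density map and hot-spot gradual extinction selection.

A candidate grid of FOV positions is scored by the immunopositive-marker
count inside each window.  Fields are chosen greedily, but every already
selected field depresses the score of nearby candidates through the
penalty

    penalty = 1 - rho * sum_i d_i ** -0.5

with d_i the Euclidean distance (in FOV widths) to selected field i,
clamped below at 0 and applied multiplicatively to the raw count.  This
"gradual extinction" spreads selections across distinct high-density
regions while a strongly dominant region still retains all selections.

Small specimens get fewer fields: below 500 FOV-equivalents the field
count is floor(area * 20 / 500); specimens of low compact area also have
rho reduced in proportion to area / 100 FOV or effective radius / 6
FOV-circle radii, whichever margin is missed harder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .slide_io import FovGeometry

#: Default penalty strength (distance measured in FOV widths).
DEFAULT_RHO = 0.3
#: Hard cap on selected fields and the specimen-area normalizer.
MAX_FIELDS = 20
AREA_NORM_FOVS = 500.0
#: Compactness margins: specimen area (FOVs) and effective radius (radii of
#: a circle with one FOV's area).
AREA_MARGIN_FOVS = 100.0
RADIUS_MARGIN = 6.0


@dataclass
class DensityMap:
    """Immunopositive counts per candidate FOV position."""

    counts: np.ndarray  # (ny, nx) int
    valid: np.ndarray  # (ny, nx) bool: tumour coverage above threshold
    origin_xy: tuple[int, int]
    stride_xy: tuple[int, int]
    fov: FovGeometry

    def center_xy(self, iy: int, ix: int) -> tuple[float, float]:
        x0 = self.origin_xy[0] + ix * self.stride_xy[0]
        y0 = self.origin_xy[1] + iy * self.stride_xy[1]
        return x0 + self.fov.width_px / 2.0, y0 + self.fov.height_px / 2.0

    def rect(self, iy: int, ix: int) -> tuple[int, int, int, int]:
        return (
            self.origin_xy[0] + ix * self.stride_xy[0],
            self.origin_xy[1] + iy * self.stride_xy[1],
            self.fov.width_px,
            self.fov.height_px,
        )


@dataclass
class PenaltyState:
    """Selected FOV centers, with distances expressed in FOV widths."""

    rho: float
    fov_width_px: float
    selected_xy: list = field(default_factory=list)


@dataclass
class HotspotField:
    rank: int
    rect_level0: tuple[int, int, int, int]  # x0, y0, w, h in level-0 px
    rect_working: tuple[int, int, int, int]
    raw_count: int
    penalized_score: float
    ki67_index: float | None = None


@dataclass
class HotspotSet:
    fields: list
    rho: float
    n_max: int
    area_fovs: float

    def __len__(self) -> int:
        return len(self.fields)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "rank": f.rank,
                "x0": f.rect_level0[0],
                "y0": f.rect_level0[1],
                "width": f.rect_level0[2],
                "height": f.rect_level0[3],
                "raw_count": f.raw_count,
                "penalized_score": f.penalized_score,
                "ki67_index": f.ki67_index,
            }
            for f in self.fields
        ]
        cols = ["rank", "x0", "y0", "width", "height",
                "raw_count", "penalized_score", "ki67_index"]
        return pd.DataFrame(rows, columns=cols)


def _integral(arr: np.ndarray) -> np.ndarray:
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    ii[1:, 1:] = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    return ii


def _box_sum(ii: np.ndarray, y0, y1, x0, x1):
    return ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]


def density_map(
    centroids_xy: np.ndarray,
    tumour_mask: np.ndarray,
    fov: FovGeometry,
    stride_xy: tuple[int, int] | None = None,
    min_coverage: float = 0.5,
) -> DensityMap:
    """Count markers inside every candidate FOV rectangle.

    Rectangles are half-open; the candidate grid starts at (0, 0) with a
    stride of half a FOV per axis by default.  Candidates whose tumour-mask
    coverage is below ``min_coverage`` are marked invalid.
    """
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    H, W = tumour_mask.shape
    fw, fh = fov.width_px, fov.height_px
    if fw > W or fh > H:
        raise ValidationError(f"FOV {fw}x{fh} larger than image {W}x{H}")
    if stride_xy is None:
        stride_xy = (max(fw // 2, 1), max(fh // 2, 1))
    sx, sy = stride_xy

    cell_count = np.zeros((H, W), dtype=np.float64)
    centroids_xy = np.asarray(centroids_xy).reshape(-1, 2)
    for x, y in centroids_xy:
        xi, yi = int(x), int(y)
        if 0 <= yi < H and 0 <= xi < W:
            cell_count[yi, xi] += 1
    ii_count = _integral(cell_count)
    ii_mask = _integral(tumour_mask.astype(np.float64))

    xs = np.arange(0, W - fw + 1, sx)
    ys = np.arange(0, H - fh + 1, sy)
    counts = np.zeros((len(ys), len(xs)), dtype=np.int64)
    valid = np.zeros((len(ys), len(xs)), dtype=bool)
    for iy, y0 in enumerate(ys):
        c = _box_sum(ii_count, y0, y0 + fh, xs, xs + fw)
        m = _box_sum(ii_mask, y0, y0 + fh, xs, xs + fw)
        counts[iy] = np.round(c).astype(np.int64)
        valid[iy] = m / (fw * fh) >= min_coverage
    return DensityMap(
        counts=counts,
        valid=valid,
        origin_xy=(0, 0),
        stride_xy=(sx, sy),
        fov=fov,
    )


def penalty(candidate_xy: tuple[float, float], state: PenaltyState) -> float:
    """Penalty factor for a candidate given the already selected fields.

    ``1 - rho * sum_i d_i ** -0.5`` with d_i in FOV widths, clamped at 0;
    equals 1 for an empty selected set.  A zero distance (the candidate is
    already selected) is an error.
    """
    if not state.selected_xy:
        return 1.0
    cx, cy = candidate_xy
    total = 0.0
    for (sx, sy) in state.selected_xy:
        d = np.hypot(cx - sx, cy - sy) / state.fov_width_px
        if d == 0:
            raise ValidationError("candidate coincides with a selected field")
        total += d**-0.5
    return max(1.0 - state.rho * total, 0.0)


def max_hotspot_count(specimen_area_in_fovs: float) -> int:
    """Number of fields allowed for a specimen of the given area (in FOVs).

    floor(area * 20 / 500) below 500 FOV-equivalents, else the standard 20.
    """
    if specimen_area_in_fovs < 0:
        raise ValidationError("specimen area must be non-negative")
    if specimen_area_in_fovs >= AREA_NORM_FOVS:
        return MAX_FIELDS
    return int(np.floor(specimen_area_in_fovs * MAX_FIELDS / AREA_NORM_FOVS))


def compactness_adjusted_rho(
    rho: float,
    specimen_area_in_fovs: float,
    effective_radius_in_fov_circle_radii: float,
) -> float:
    """Reduce rho for low-compactness specimens.

    The reference margins are 100 FOV of area and six radii of a circular
    field with one FOV's area; rho shrinks by min(1, area/100, radius/6).
    """
    if specimen_area_in_fovs < 0 or effective_radius_in_fov_circle_radii < 0:
        raise ValidationError("compactness inputs must be non-negative")
    factor = min(
        1.0,
        specimen_area_in_fovs / AREA_MARGIN_FOVS,
        effective_radius_in_fov_circle_radii / RADIUS_MARGIN,
    )
    return rho * factor


def select_hotspots(
    dmap: DensityMap,
    rho: float = DEFAULT_RHO,
    n_max: int = MAX_FIELDS,
    area_fovs: float | None = None,
    downsample: float = 1.0,
    ki67_fn=None,
) -> HotspotSet:
    """Greedy selection with gradual extinction.

    Each iteration scores every valid candidate as raw count times the
    current penalty, picks the maximum (ties: higher raw count, then
    row-major grid order) and stops after ``n_max`` fields or when no
    candidate with a positive raw count remains.  With rho = 0 this reduces
    to plain greedy top-k by count.  ``ki67_fn(rect_working)`` computes the
    per-field Ki-67 index when provided.
    """
    if rho < 0:
        raise ConfigError("rho must be >= 0")
    valid = dmap.valid & (dmap.counts > 0)
    iys, ixs = np.nonzero(valid)
    if len(iys) == 0:
        import warnings

        warnings.warn("no valid hot-spot candidates")
        return HotspotSet([], rho=rho, n_max=n_max, area_fovs=area_fovs or 0.0)

    centers = np.array([dmap.center_xy(iy, ix) for iy, ix in zip(iys, ixs)])
    raw = dmap.counts[iys, ixs].astype(np.float64)
    order_key = iys * dmap.counts.shape[1] + ixs  # row-major tie break
    pen = np.ones(len(raw))
    chosen: list[int] = []
    fields = []
    fov_w = float(dmap.fov.width_px)
    for rank in range(1, n_max + 1):
        score = raw * pen
        score[chosen] = -np.inf
        best = np.lexsort((order_key, -raw, -score))[0]
        if not np.isfinite(score[best]) or raw[best] <= 0:
            break
        chosen.append(best)
        iy, ix = iys[best], ixs[best]
        rect_w = dmap.rect(iy, ix)
        rect0 = tuple(int(round(v * downsample)) for v in rect_w)
        fields.append(
            HotspotField(
                rank=rank,
                rect_level0=rect0,
                rect_working=rect_w,
                raw_count=int(raw[best]),
                penalized_score=float(score[best]),
                ki67_index=ki67_fn(rect_w) if ki67_fn else None,
            )
        )
        # update penalties: subtract rho * d^-0.5 towards the new field
        d = np.hypot(centers[:, 0] - centers[best, 0], centers[:, 1] - centers[best, 1]) / fov_w
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(d > 0, rho * d**-0.5, np.inf)
        pen = np.maximum(pen - contrib, 0.0)
    return HotspotSet(fields, rho=rho, n_max=n_max, area_fovs=area_fovs or 0.0)
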