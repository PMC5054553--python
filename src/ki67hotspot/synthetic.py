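"""Seeded synthetic histology-like slides with complete ground truth.

The generator emulates what a Ki-67/MIB-1 stained meningioma section looks
like at eight-fold reduced scan resolution: immunopositive (DAB, dark
brown) and immunonegative (hematoxylin, pale blue) nuclei a few pixels
across, hemorrhage patches of erythrocyte-red, darker compressed-texture
fold bands, thin brown curvilinear vessel walls, and small near-black color
artifacts -- each recorded in a per-class ground-truth mask.  Identical
spec + seed produce bit-identical outputs.

It emulates composition and palette, not photorealistic staining or
scanner noise; see the methods note for what that implies about tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

from .errors import ValidationError
from .masks import MaskRole, RegionMask
from .slide_io import SlideImage

# Class palettes (RGB).  Hues approximate DAB / hematoxylin staining at
# reduced resolution: DAB-positive nuclei are much darker than the pale
# hematoxylin counterstain, which is what lets an h-depth criterion on
# luminance separate the two.
BACKGROUND_WHITE = (255, 255, 255)
TISSUE_BASE = (199, 181, 214)
DAB_BROWN = (91, 59, 29)
HEMATOXYLIN_BLUE = (150, 155, 205)
HEMORRHAGE_RED = (170, 72, 56)
VESSEL_BROWN = (132, 84, 40)
ARTIFACT_BLACK = (5, 5, 5)
FOLD_DARKEN = 0.62

#: Default working resolution (8 x 0.38895 um/px).
DEFAULT_UM_PER_PX = 8 * 0.38895

PALETTE = {
    "tissue": TISSUE_BASE,
    "pos": DAB_BROWN,
    "neg": HEMATOXYLIN_BLUE,
    "hemorrhage": HEMORRHAGE_RED,
    "vessel": VESSEL_BROWN,
    "artifact": ARTIFACT_BLACK,
}


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic slide."""

    width_px: int = 512
    height_px: int = 512
    um_per_px: float = DEFAULT_UM_PER_PX
    n_pos_cells: int = 0
    n_neg_cells: int = 0
    cell_radius_px: int = 2
    #: dense immunopositive clusters: (center_xy, radius_px, n_cells)
    pos_clusters: list = field(default_factory=list)
    #: (center_xy, radius_px)
    hemorrhage_blobs: list = field(default_factory=list)
    #: (polyline [(x, y), ...], band_width_px)
    fold_bands: list = field(default_factory=list)
    #: (polyline [(x, y), ...], wall_thickness_px)
    vessel_walls: list = field(default_factory=list)
    artifact_pixels: int = 0
    background_rgb: tuple = BACKGROUND_WHITE
    #: tissue ellipses (center_xy, semi_axis_x, semi_axis_y); None = one
    #: centered ellipse with an 8% margin
    tissue_ellipses: list | None = None
    blur_sigma: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValidationError("image dimensions must be positive")
        for name in ("n_pos_cells", "n_neg_cells", "artifact_pixels"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.cell_radius_px < 1:
            raise ValidationError("cell_radius_px must be >= 1")
        w, h = self.width_px, self.height_px

        def _inside(x, y, what):
            if not (0 <= x < w and 0 <= y < h):
                raise ValidationError(f"{what} at ({x}, {y}) outside image bounds")

        for k, (c, r) in enumerate(self.hemorrhage_blobs):
            _inside(c[0] - r, c[1] - r, f"hemorrhage_blobs[{k}]")
            _inside(c[0] + r, c[1] + r, f"hemorrhage_blobs[{k}]")
        for k, (c, r, _n) in enumerate(self.pos_clusters):
            _inside(c[0] - r, c[1] - r, f"pos_clusters[{k}]")
            _inside(c[0] + r, c[1] + r, f"pos_clusters[{k}]")
        for k, (poly, width) in enumerate(list(self.fold_bands) + list(self.vessel_walls)):
            what = (
                f"fold_bands[{k}]" if k < len(self.fold_bands)
                else f"vessel_walls[{k - len(self.fold_bands)}]"
            )
            for (x, y) in poly:
                _inside(x - width / 2, y - width / 2, what)
                _inside(x + width / 2, y + width / 2, what)


@dataclass
class GroundTruth:
    """Everything the generator placed, for downstream oracles."""

    pos_centroids: np.ndarray  # (n, 2) as (x, y)
    neg_centroids: np.ndarray
    masks: dict  # role name -> bool raster
    achieved_pos: int = 0
    achieved_neg: int = 0

    def region_mask(self, role: str) -> RegionMask:
        return RegionMask(self.masks[role], MaskRole(role))


def _ellipse_mask(shape, center_xy, ax, ay):
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    return ((xx - center_xy[0]) / ax) ** 2 + ((yy - center_xy[1]) / ay) ** 2 <= 1.0


def _polyline_band(shape, polyline, width) -> np.ndarray:
    """Band of ``width`` around a polyline, via distance to rasterized segments."""
    H, W = shape
    canvas = np.zeros(shape, bool)
    pts = np.asarray(polyline, dtype=np.float64)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        n = int(max(abs(x1 - x0), abs(y1 - y0), 1)) * 2 + 1
        xs = np.clip(np.round(np.linspace(x0, x1, n)).astype(int), 0, W - 1)
        ys = np.clip(np.round(np.linspace(y0, y1, n)).astype(int), 0, H - 1)
        canvas[ys, xs] = True
    dist = ndi.distance_transform_edt(~canvas)
    return dist <= width / 2.0


def _paint_disk(img, cx, cy, radius, color):
    """Alpha-blend an anti-aliased disk into ``img`` (float RGB)."""
    H, W = img.shape[:2]
    r_out = int(np.ceil(radius + 1))
    x0, x1 = max(cx - r_out, 0), min(cx + r_out + 1, W)
    y0, y1 = max(cy - r_out, 0), min(cy + r_out + 1, H)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    alpha = np.clip(radius + 0.5 - d, 0.0, 1.0)[..., None]
    img[y0:y1, x0:x1] = (1 - alpha) * img[y0:y1, x0:x1] + alpha * np.asarray(color, float)


def _place_points(rng, allowed, n, min_sep, max_tries_per_point=60, taken=None):
    """Rejection-sample ``n`` points inside ``allowed`` with pairwise
    separation >= ``min_sep`` (also against ``taken``).  Returns what was
    achievable within the retry cap."""
    H, W = allowed.shape
    ys, xs = np.nonzero(allowed)
    if ys.size == 0 or n == 0:
        return []
    cell = max(min_sep, 1.0)
    grid: dict[tuple[int, int], list] = {}

    def _register(p):
        grid.setdefault((int(p[0] // cell), int(p[1] // cell)), []).append(p)

    def _clear(p):
        gy, gx = int(p[0] // cell), int(p[1] // cell)
        for ny in (gy - 1, gy, gy + 1):
            for nx in (gx - 1, gx, gx + 1):
                for q in grid.get((ny, nx), ()):
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_sep**2:
                        return False
        return True

    for p in taken or []:
        _register(p)
    placed = []
    for _ in range(n):
        for _try in range(max_tries_per_point):
            k = rng.integers(0, ys.size)
            p = (int(ys[k]), int(xs[k]))
            if _clear(p):
                placed.append(p)
                _register(p)
                break
    return placed


def generate_slide(spec: SyntheticSpec) -> tuple[SlideImage, GroundTruth]:
    """Render the slide described by ``spec`` and its ground truth.

    Placement uses rejection sampling with a retry cap; the achieved cell
    counts are always reported in the ground truth.  Nuclei are rendered as
    anti-aliased disks and the whole image receives a light Gaussian blur,
    mimicking how few-pixel nuclei appear at eight-fold reduction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    shape = (H, W)
    img = np.ones((H, W, 3), np.float64) * np.asarray(spec.background_rgb, float)

    # --- tissue region -------------------------------------------------
    if spec.tissue_ellipses is None:
        ellipses = [((W / 2, H / 2), W * 0.42, H * 0.42)]
    else:
        ellipses = spec.tissue_ellipses
    tissue = np.zeros(shape, bool)
    for c, ax, ay in ellipses:
        tissue |= _ellipse_mask(shape, c, ax, ay)

    base = np.asarray(TISSUE_BASE, float)
    noise = rng.normal(0.0, 2.5, size=(H, W, 3))
    mottle = ndi.gaussian_filter(rng.normal(0.0, 8.0, size=shape), 9.0)[..., None]
    img[tissue] = base + noise[tissue] + mottle[tissue]

    # --- hemorrhage patches -------------------------------------------
    hem = np.zeros(shape, bool)
    for c, r in spec.hemorrhage_blobs:
        hem |= _ellipse_mask(shape, c, r, r)
    hem &= tissue
    if hem.any():
        speckle = ndi.gaussian_filter(rng.normal(0.0, 30.0, size=shape), 1.2)[..., None]
        img[hem] = np.asarray(HEMORRHAGE_RED, float) + noise[hem] * 0.5 + speckle[hem]

    # --- folds: darkened, density-doubled texture ----------------------
    fold = np.zeros(shape, bool)
    for poly, width in spec.fold_bands:
        fold |= _polyline_band(shape, poly, width)
    fold &= tissue
    if fold.any():
        crush = ndi.gaussian_filter(rng.normal(0.0, 55.0, size=shape), 1.0)[..., None]
        img[fold] = img[fold] * FOLD_DARKEN + np.abs(crush[fold]) * -0.3

    # --- vessel walls ---------------------------------------------------
    vessel = np.zeros(shape, bool)
    for poly, thickness in spec.vessel_walls:
        vessel |= _polyline_band(shape, poly, thickness)
    vessel &= tissue
    if vessel.any():
        img[vessel] = np.asarray(VESSEL_BROWN, float) + noise[vessel] * 0.6

    # --- nuclei ---------------------------------------------------------
    structure = hem | fold | vessel
    clean = tissue & ~structure
    min_sep = 2 * spec.cell_radius_px + 2
    r_cell = spec.cell_radius_px

    neg_pts = _place_points(rng, clean, spec.n_neg_cells, min_sep)
    pos_pts = _place_points(rng, clean, spec.n_pos_cells, min_sep, taken=neg_pts)
    cluster_pts = []
    for c, radius, n in spec.pos_clusters:
        zone = _ellipse_mask(shape, c, radius, radius) & tissue
        cluster_pts += _place_points(
            rng, zone, n, min_sep, taken=neg_pts + pos_pts + cluster_pts
        )
    pos_pts = pos_pts + cluster_pts

    for (y, x) in neg_pts:
        _paint_disk(img, x, y, r_cell, HEMATOXYLIN_BLUE)
    for (y, x) in pos_pts:
        _paint_disk(img, x, y, r_cell, DAB_BROWN)

    # --- small near-black color artifacts -------------------------------
    artifact = np.zeros(shape, bool)
    remaining = spec.artifact_pixels
    ys, xs = np.nonzero(tissue)
    while remaining > 0 and ys.size:
        k = rng.integers(0, ys.size)
        blob = int(min(remaining, rng.integers(3, 9)))
        cy, cx = int(ys[k]), int(xs[k])
        placed = 0
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                if placed >= blob:
                    break
                py, px = cy + dy, cx + dx
                if 0 <= py < H and 0 <= px < W and tissue[py, px]:
                    artifact[py, px] = True
                    placed += 1
        remaining -= max(placed, 1)
    if artifact.any():
        img[artifact] = np.asarray(ARTIFACT_BLACK, float)

    # --- blur and quantize ----------------------------------------------
    if spec.blur_sigma > 0:
        for ch in range(3):
            img[..., ch] = ndi.gaussian_filter(img[..., ch], spec.blur_sigma)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if artifact.any():  # keep artifact cores genuinely near-black after blur
        img[artifact] = ARTIFACT_BLACK

    def _disk_mask(points):
        m = np.zeros(shape, bool)
        for (y, x) in points:
            y0, y1 = max(y - r_cell, 0), min(y + r_cell + 1, H)
            x0, x1 = max(x - r_cell, 0), min(x + r_cell + 1, W)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            m[y0:y1, x0:x1] |= (yy - y) ** 2 + (xx - x) ** 2 <= r_cell**2
        return m

    gt = GroundTruth(
        pos_centroids=np.array([(x, y) for (y, x) in pos_pts], dtype=np.int64).reshape(-1, 2),
        neg_centroids=np.array([(x, y) for (y, x) in neg_pts], dtype=np.int64).reshape(-1, 2),
        masks={
            "tissue": tissue,
            "hemorrhage": hem,
            "fold": fold,
            "vessel": vessel,
            "artifact": artifact,
            "excluded": ~tissue,
            "pos_cells": _disk_mask(pos_pts),
            "neg_cells": _disk_mask(neg_pts),
        },
        achieved_pos=len(pos_pts),
        achieved_neg=len(neg_pts),
    )
    slide = SlideImage(pixels=img, um_per_px=spec.um_per_px, level=0, downsample=1.0)
    return slide, gt


def texture_patch(kind: str, size: int, seed: int, cell_radius_px: int = 2) -> np.ndarray:
    """A small single-class RGB patch (tumour / hemorrhage / fold) for
    classifier training, rendered with the same palettes as full slides."""
    rng = np.random.default_rng(seed)
    base = np.asarray(TISSUE_BASE, float)
    img = np.ones((size, size, 3), np.float64) * base
    img += rng.normal(0.0, 2.5, size=img.shape)
    if kind == "hemorrhage":
        speckle = ndi.gaussian_filter(rng.normal(0.0, 30.0, size=(size, size)), 1.2)[..., None]
        img[:] = np.asarray(HEMORRHAGE_RED, float) + rng.normal(0, 2, img.shape) + speckle
    elif kind in ("tumour", "fold"):
        density = 0.004 if kind == "tumour" else 0.009
        n = max(int(size * size * density), 3)
        pts = _place_points(rng, np.ones((size, size), bool), n, 2 * cell_radius_px + 1)
        for (y, x) in pts:
            color = DAB_BROWN if rng.random() < 0.3 else HEMATOXYLIN_BLUE
            _paint_disk(img, x, y, cell_radius_px, color)
        if kind == "fold":
            crush = ndi.gaussian_filter(rng.normal(0.0, 55.0, size=(size, size)), 1.0)
            img = img * FOLD_DARKEN - np.abs(crush)[..., None] * 0.3
    else:
        raise ValidationError(f"unknown texture kind {kind!r}")
    for ch in range(3):
        img[..., ch] = ndi.gaussian_filter(img[..., ch], 0.8)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def verify_palette_separation(
    image: np.ndarray, gt: GroundTruth, min_distance: float = 25.0
) -> dict[str, float]:
    """Mean rendered color distance of each class from the tissue base.

    Returns the per-class Euclidean RGB distances; raises ValidationError
    if any rendered class mean is closer than ``min_distance``.
    """
    out = {}
    ref = np.asarray(TISSUE_BASE, float)
    for role in ("pos_cells", "neg_cells", "hemorrhage", "fold", "vessel", "artifact"):
        m = gt.masks.get(role)
        if m is None or not m.any():
            continue
        dist = float(np.linalg.norm(image[m].mean(axis=0) - ref))
        out[role] = dist
        if dist < min_distance:
            raise ValidationError(f"class {role} mean color too close to tissue ({dist:.1f})")
    return out


def save_outputs(out_dir: str | Path, slide: SlideImage, gt: GroundTruth) -> None:
    """Write the rendered PNG, per-class mask PNGs and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(slide.pixels).save(out / "slide.png")
    for role, m in gt.masks.items():
        Image.fromarray((m.astype(np.uint8)) * 255).save(out / f"mask_{role}.png")
    payload = {
        "um_per_px": slide.um_per_px,
        "achieved_pos": gt.achieved_pos,
        "achieved_neg": gt.achieved_neg,
        "pos_centroids": gt.pos_centroids.tolist(),
        "neg_centroids": gt.neg_centroids.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))


def spec_from_json(path: str | Path) -> SyntheticSpec:
    data = json.loads(Path(path).read_text())
    return SyntheticSpec(**data)


def large_specimen_spec(
    seed: int,
    n_clusters: int = 45,
    cells_per_cluster: int = 55,
    cluster_radius_px: int = 60,
) -> SyntheticSpec:
    """The standard large-specimen scenario: tissue area above the
    500-FOV-equivalent threshold with abundant well-separated dense
    immunopositive clusters.

    A 4000 x 2400 px slide at eight-fold-reduction resolution whose tissue
    ellipse covers about 546 FOV-equivalents; cluster centers sit on a
    coarse grid (spacing well above one FOV) restricted to the inner 85%
    of the ellipse, capped at ``n_clusters``.
    """
    W, H = 4000, 2400
    cx, cy, ax, ay = W / 2, H / 2, 1890, 1130
    centers = []
    for gy in range(300, H - 200, 300):
        for gx in range(400, W - 300, 400):
            if ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 <= 0.85**2:
                centers.append((gx, gy))
    centers = centers[:n_clusters]
    return SyntheticSpec(
        width_px=W,
        height_px=H,
        n_pos_cells=2000,
        n_neg_cells=12000,
        pos_clusters=[(c, cluster_radius_px, cells_per_cluster) for c in centers],
        tissue_ellipses=[((cx, cy), ax, ay)],
        seed=seed,
    )
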