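"""Slide reading and the coordinate / field-of-view conventions.

Whole-slide pyramids are read through tifffile (SubIFD or multi-level
series); plain PNG/TIFF rasters are treated as level 0 with a user-supplied
resolution.  All coordinates are 0-based, x rightward, y downward, and
rectangles are half-open ``[x0, x1) x [y0, y1)``.  Results reported
downstream are mapped back to level-0 pixel space.

The reference field of view is the 1024 x 766 px rectangle at the scanner's
full resolution of 0.38895 um/px (matching a 400x microscope field of about
0.12 mm^2).  Analysis runs at a reduced level; the level whose downsample is
closest to 8 is auto-selected, since eight-fold reduction still preserves
recognizability of individual nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import ConfigError, ShapeError

#: Full-resolution FOV size in pixels (width, height).
FULL_RES_FOV_PX = (1024, 766)
#: Full (level-0) scanner resolution in micrometres per pixel.
FULL_RES_UM_PER_PX = 0.38895
#: Default working downsample factor.
DEFAULT_WORKING_DOWNSAMPLE = 8


@dataclass
class SlideImage:
    """An RGB raster with physical pixel size and pyramid provenance."""

    pixels: np.ndarray
    um_per_px: float
    level: int = 0
    downsample: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ShapeError(f"slide pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.um_per_px <= 0:
            raise ConfigError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def to_level0(self, x: float, y: float) -> tuple[float, float]:
        """Map working-level coordinates to level-0 pixel space."""
        return x * self.downsample, y * self.downsample

    def rect_to_level0(self, x0: int, y0: int, w: int, h: int) -> tuple[int, int, int, int]:
        d = self.downsample
        return (int(round(x0 * d)), int(round(y0 * d)), int(round(w * d)), int(round(h * d)))


@dataclass(frozen=True)
class FovGeometry:
    """Evaluation-field geometry at a given resolution."""

    width_px: int
    height_px: int
    um_per_px: float

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.um_per_px / 1000.0) ** 2

    @property
    def area_px(self) -> int:
        return self.width_px * self.height_px

    @property
    def circle_radius_px(self) -> float:
        """Radius of a circular field with the same area as one FOV."""
        return float(np.sqrt(self.area_px / np.pi))


def fov_geometry(um_per_px: float) -> FovGeometry:
    """FOV dimensions at an arbitrary resolution.

    The full-resolution 1024 x 766 px field is rescaled by
    ``FULL_RES_UM_PER_PX / um_per_px`` and rounded to the nearest integer
    per axis (documented so downstream counts are reproducible).
    """
    if um_per_px <= 0:
        raise ConfigError("um_per_px must be positive")
    scale = FULL_RES_UM_PER_PX / um_per_px
    w = int(round(FULL_RES_FOV_PX[0] * scale))
    h = int(round(FULL_RES_FOV_PX[1] * scale))
    return FovGeometry(width_px=w, height_px=h, um_per_px=um_per_px)


def _read_pyramidal_tiff(path: Path, level: int | None, working_downsample: float):
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        levels = list(series.levels)
        shapes = [lvl.shape for lvl in levels]
        base_w = shapes[0][1] if len(shapes[0]) >= 2 else shapes[0][0]
        downsamples = []
        for shp in shapes:
            w = shp[1] if len(shp) >= 2 else shp[0]
            downsamples.append(base_w / w)
        if level is None:
            level = int(np.argmin([abs(d - working_downsample) for d in downsamples]))
        if not 0 <= level < len(levels):
            raise ConfigError(
                f"level {level} unavailable: file has {len(levels)} level(s)"
            )
        arr = levels[level].asarray()
        return arr, downsamples[level], level


def read_slide(
    path: str | Path,
    level: int | None = None,
    um_per_px: float = FULL_RES_UM_PER_PX,
    working_downsample: float = DEFAULT_WORKING_DOWNSAMPLE,
) -> SlideImage:
    """Read a slide image at the working resolution.

    Parameters
    ----------
    path:
        A pyramidal TIFF (levels exposed through tifffile series/SubIFDs) or
        a plain PNG/TIFF raster.
    level:
        Pyramid level to read; ``None`` auto-selects the level whose
        downsample factor is closest to ``working_downsample``.  Plain
        rasters only have level 0.
    um_per_px:
        Resolution of level 0 in micrometres per pixel; the returned
        slide's resolution is scaled by the level's downsample factor.

    Black (0, 0, 0) pixels are preserved untouched: they mark non-scanned
    regions and are recognized as non-tissue downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr, downsample, level = _read_pyramidal_tiff(path, level, working_downsample)
    else:
        if level not in (None, 0):
            raise ConfigError(f"plain raster {path.name} only has level 0, asked for {level}")
        arr = np.asarray(Image.open(path).convert("RGB"))
        downsample, level = 1.0, 0
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return SlideImage(
        pixels=arr,
        um_per_px=um_per_px * downsample,
        level=level,
        downsample=downsample,
    )
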