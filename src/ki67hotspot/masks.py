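"""Binary region masks aligned to a slide raster, labelled by role."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ShapeError


class MaskRole(str, Enum):
    TISSUE = "tissue"
    HEMORRHAGE = "hemorrhage"
    FOLD = "fold"
    VESSEL = "vessel"
    ARTIFACT = "artifact"
    EXCLUDED = "excluded"


@dataclass
class RegionMask:
    """A binary raster aligned to its source image, labelled by role.

    The role is set exactly once at construction; ``level`` records the
    pyramid level the mask was computed at.
    """

    mask: np.ndarray
    role: MaskRole
    level: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.role = MaskRole(self.role)
        if self.mask.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got ndim={self.mask.ndim}")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def require_same_shape(self, other: "RegionMask | np.ndarray") -> None:
        other_shape = other.mask.shape if isinstance(other, RegionMask) else other.shape
        if self.mask.shape != other_shape:
            raise ShapeError(
                f"mask shapes differ: {self.mask.shape} vs {other_shape}"
            )
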