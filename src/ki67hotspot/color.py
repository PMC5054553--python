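"""Color representations the pipeline depends on.

The artifact classifiers work on a composite plane ``u * 512 + C`` (u from
CIE Luv, C from CMYK), vessel-wall detection uses the Y plane of CMYK, and
immunopositive-cell segmentation uses Luv luminance.  sRGB companding with
the D65 white point is the fixed convention throughout; the reference white
is taken as the sRGB matrix applied to (1, 1, 1) so that the neutral (gray)
axis maps exactly to u = v = 0.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hed

from .errors import ShapeError

# sRGB (linear) -> XYZ, D65.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE_XYZ = _SRGB_TO_XYZ @ np.ones(3)
_EPS = 216.0 / 24389.0  # (6/29)^3, CIE junction point
_KAPPA = 24389.0 / 27.0

#: Scale mapping hematoxylin optical density onto an L-like 0-100 range.
HEMATOXYLIN_PLANE_SCALE = 300.0


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ShapeError(f"expected an RGB raster (H, W, 3), got shape {image.shape}")
    return image


def _srgb_to_linear(rgb01: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(rgb01 <= 0.04045, rgb01 / 12.92, ((rgb01 + a) / (1 + a)) ** 2.4)


def rgb_to_luv(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit RGB raster to CIE L*, u*, v* planes.

    Returns ``(L, u, v)`` with L in [0, 100] and u, v in their native CIE
    scale.  Black pixels (X = Y = Z = 0) map to L = u = v = 0.
    """
    rgb = _as_rgb(image).astype(np.float64) / 255.0
    xyz = _srgb_to_linear(rgb) @ _SRGB_TO_XYZ.T
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]

    t = Y / _WHITE_XYZ[1]
    L = np.where(t > _EPS, 116.0 * np.cbrt(t) - 16.0, _KAPPA * t)

    denom = X + 15.0 * Y + 3.0 * Z
    wd = _WHITE_XYZ[0] + 15.0 * _WHITE_XYZ[1] + 3.0 * _WHITE_XYZ[2]
    u_prime_n = 4.0 * _WHITE_XYZ[0] / wd
    v_prime_n = 9.0 * _WHITE_XYZ[1] / wd
    with np.errstate(invalid="ignore", divide="ignore"):
        u_prime = np.where(denom > 0, 4.0 * X / np.where(denom > 0, denom, 1.0), u_prime_n)
        v_prime = np.where(denom > 0, 9.0 * Y / np.where(denom > 0, denom, 1.0), v_prime_n)
    u = 13.0 * L * (u_prime - u_prime_n)
    v = 13.0 * L * (v_prime - v_prime_n)
    return L, u, v


def luminance(image: np.ndarray) -> np.ndarray:
    """CIE L* (0-100) of an 8-bit RGB raster."""
    return rgb_to_luv(image)[0]


def rgb_to_cmyk(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Naive RGB -> CMYK conversion with all planes in [0, 1].

    K = 1 - max(R, G, B)/255; C = (1 - R/255 - K)/(1 - K) and analogously
    for M, Y.  Pure black (K = 1) gets C = M = Y = 0 by convention.
    """
    rgb = _as_rgb(image).astype(np.float64) / 255.0
    K = 1.0 - rgb.max(axis=-1)
    denom = 1.0 - K
    safe = np.where(denom > 0, denom, 1.0)
    C = np.where(denom > 0, (1.0 - rgb[..., 0] - K) / safe, 0.0)
    M = np.where(denom > 0, (1.0 - rgb[..., 1] - K) / safe, 0.0)
    Y = np.where(denom > 0, (1.0 - rgb[..., 2] - K) / safe, 0.0)
    return C, M, Y, K


def composite_channel(u: np.ndarray, c: np.ndarray) -> np.ndarray:
    """The composite texture plane ``u * 512 + C``.

    The 512 multiplier makes u (chromatic red-green shift, which separates
    hemorrhage from tumour irrespective of immunopositive-cell density)
    dominant over C by construction.
    """
    u = np.asarray(u, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    if u.shape != c.shape:
        raise ShapeError(f"misaligned planes: {u.shape} vs {c.shape}")
    return u * 512.0 + c


def hematoxylin_plane(image: np.ndarray) -> np.ndarray:
    """L-like plane in which hematoxylin-stained (immunonegative) nuclei are wells.

    Uses the hematoxylin channel of the Ruifrok-Johnston stain-separation
    (rgb2hed) and maps optical density onto a descending 0-100-like scale:
    high hematoxylin density -> low plane value.
    """
    rgb = _as_rgb(image).astype(np.float64) / 255.0
    h_density = rgb2hed(rgb)[..., 0]
    return 100.0 - HEMATOXYLIN_PLANE_SCALE * h_density


def color_planes(image: np.ndarray) -> dict[str, np.ndarray]:
    """All planes used by the pipeline, keyed by a stable plane identifier."""
    L, u, v = rgb_to_luv(image)
    C, M, Y, K = rgb_to_cmyk(image)
    return {
        "L": L,
        "u": u,
        "v": v,
        "C": C,
        "M": M,
        "Y": Y,
        "K": K,
        "composite_uC": composite_channel(u, C),
        "hematoxylin": hematoxylin_plane(image),
    }
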