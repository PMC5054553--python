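"""Local texture descriptors over circular neighborhoods.

Two descriptor families are provided:

* Unser features -- the eight statistics (mean, variance, homogeneity,
  contrast, energy, correlation, cluster shade, cluster prominence)
  computed from normalized histograms of pixel-pair sums and differences
  inside a circular neighborhood Omega.  Sum/difference histograms
  approximate co-occurrence statistics at a fraction of the cost.
* Local Binary Patterns (LBP) -- normalized histograms of circular-sampling
  binary codes accumulated over Omega, in uniform, rotation-invariant, or
  uniform rotation-invariant form.

Gray levels are quantized to a fixed number of bins (default 64) before
histogramming.  The quantization grid is anchored at the plane minimum, so
an image-wide intensity offset leaves every feature except the Unser mean
unchanged; the step is fixed per plane identifier (PLANE_QUANT_STEPS) when
features from different images must share units, and falls back to the
plane's own dynamic range otherwise.
Feature extraction accepts independent radii for training and testing, so
classifier training can use a slightly larger neighborhood (higher data
integrity within a class) than prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import local_binary_pattern

from .errors import ConfigError, ValidationError

UNSER_FEATURE_NAMES = (
    "mean",
    "variance",
    "homogeneity",
    "contrast",
    "energy",
    "correlation",
    "cluster_shade",
    "cluster_prominence",
)

#: Quantization levels applied to a plane before sum/difference histogramming.
DEFAULT_QUANT_LEVELS = 64
#: Fixed quantization step per plane identifier, so features computed on a
#: small training patch and on a whole slide share their gray-level units.
#: Each step spans the plane's realistic dynamic range over the 64 levels.
PLANE_QUANT_STEPS = {
    "L": 100.0 / DEFAULT_QUANT_LEVELS,
    "hematoxylin": 100.0 / DEFAULT_QUANT_LEVELS,
    "u": 200.0 / DEFAULT_QUANT_LEVELS,
    "v": 200.0 / DEFAULT_QUANT_LEVELS,
    "C": 1.0 / DEFAULT_QUANT_LEVELS,
    "M": 1.0 / DEFAULT_QUANT_LEVELS,
    "Y": 1.0 / DEFAULT_QUANT_LEVELS,
    "K": 1.0 / DEFAULT_QUANT_LEVELS,
    "composite_uC": 45000.0 / DEFAULT_QUANT_LEVELS,
}
#: Unit displacements averaged over (0, 45, 90, 135 degrees).
UNIT_DISPLACEMENTS = ((0, 1), (1, 1), (1, 0), (1, -1))
#: Default neighborhood radii (px): prediction and training.
DEFAULT_TEST_RADIUS = 10
DEFAULT_TRAIN_RADIUS = 12

_LBP_METHOD = {
    "uniform": "nri_uniform",
    "rotation_invariant": "ror",
    "uniform_rotation_invariant": "uniform",
}


@dataclass(frozen=True)
class UnserFeatures:
    mean: float
    variance: float
    homogeneity: float
    contrast: float
    energy: float
    correlation: float
    cluster_shade: float
    cluster_prominence: float
    radius_px: int
    plane: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in UNSER_FEATURE_NAMES])


@dataclass
class LbpDescriptor:
    histogram: np.ndarray
    radius_px: int
    n_points: int
    variant: str

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=np.float64)


def quantize_plane(
    plane: np.ndarray, levels: int = DEFAULT_QUANT_LEVELS, step: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Quantize a float plane to ``levels`` gray levels.

    Returns ``(q, vmin, step)`` where ``q`` is integer in [0, levels) and
    the original value of bin i is approximately ``vmin + i * step``.  The
    grid is anchored at the plane minimum, so an image-wide offset leaves
    the quantized image unchanged (exact offset invariance); values beyond
    ``levels`` steps saturate in the top bin.  With ``step=None`` the step
    is derived from the plane's own dynamic range; pass the plane's entry
    from :data:`PLANE_QUANT_STEPS` whenever features from different images
    must share units (classifier training vs. prediction).
    """
    plane = np.asarray(plane, dtype=np.float64)
    vmin = float(plane.min())
    vmax = float(plane.max())
    if step is None:
        if vmax == vmin:
            return np.zeros(plane.shape, dtype=np.int64), vmin, 1.0
        step = (vmax - vmin) / levels
    q = np.floor((plane - vmin) / step).astype(np.int64)
    np.clip(q, 0, levels - 1, out=q)
    return q, vmin, step


def disk_offsets(radius_px: int) -> np.ndarray:
    """(dy, dx) offsets of the circular neighborhood of ``radius_px``."""
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _pair_indices(offsets: np.ndarray, displacement: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) with offsets[j] == offsets[i] + displacement."""
    lookup = {tuple(o): k for k, o in enumerate(offsets)}
    ai, aj = [], []
    d = tuple(displacement)
    for k, o in enumerate(offsets):
        target = (o[0] + d[0], o[1] + d[1])
        j = lookup.get(target)
        if j is not None:
            ai.append(k)
            aj.append(j)
    if not ai:
        raise ConfigError(f"no in-neighborhood pairs for displacement {displacement}")
    return np.asarray(ai), np.asarray(aj)


def _features_from_hist_batch(
    sum_hist: np.ndarray, diff_hist: np.ndarray, levels: int, vmin: float, step: float
) -> np.ndarray:
    """Vectorized Unser features from per-row normalized histograms.

    ``sum_hist``: (n, 2*levels-1) over s = i + j; ``diff_hist``:
    (n, 2*levels-1) over d = (i - j) + levels - 1.
    """
    s_vals = np.arange(2 * levels - 1, dtype=np.float64)
    d_vals = np.arange(2 * levels - 1, dtype=np.float64) - (levels - 1)

    mu_s = sum_hist @ s_vals  # E[s] = 2 * mean (quantized units)
    centered = s_vals[None, :] - mu_s[:, None]
    m2_s = np.einsum("ij,ij->i", sum_hist, centered**2)
    m3_s = np.einsum("ij,ij->i", sum_hist, centered**3)
    m4_s = np.einsum("ij,ij->i", sum_hist, centered**4)
    m2_d = diff_hist @ d_vals**2

    mean = vmin + step * (mu_s / 2.0)
    variance = 0.5 * (m2_s + m2_d)
    contrast = m2_d
    homogeneity = diff_hist @ (1.0 / (1.0 + d_vals**2))
    energy = np.einsum("ij,ij->i", sum_hist, sum_hist) * np.einsum(
        "ij,ij->i", diff_hist, diff_hist
    )
    correlation = 0.5 * (m2_s - m2_d)
    return np.stack(
        [mean, variance, homogeneity, contrast, energy, correlation, m3_s, m4_s], axis=1
    )


def unser_feature_grid(
    plane: np.ndarray,
    centers: np.ndarray,
    radius_px: int,
    displacements: tuple[tuple[int, int], ...] = UNIT_DISPLACEMENTS,
    levels: int = DEFAULT_QUANT_LEVELS,
    batch: int = 2048,
    step: float | None = None,
) -> np.ndarray:
    """Unser features at many centers; returns an (n_centers, 8) array.

    ``centers`` are (y, x) pairs; every neighborhood must fit inside the
    plane (see :func:`valid_centers`).  Sum and difference histograms pool
    the pixel pairs of all requested displacements.
    """
    plane = np.asarray(plane, dtype=np.float64)
    centers = np.atleast_2d(np.asarray(centers, dtype=np.int64))
    q, vmin, step = quantize_plane(plane, levels, step=step)
    offsets = disk_offsets(radius_px)
    r = radius_px
    H, W = plane.shape
    if centers.size and (
        centers[:, 0].min() < r
        or centers[:, 1].min() < r
        or centers[:, 0].max() >= H - r
        or centers[:, 1].max() >= W - r
    ):
        raise ValidationError("a neighborhood exits the image; pad or skip the center")

    pair_idx = [_pair_indices(offsets, d) for d in displacements]
    n_bins = 2 * levels - 1
    out = np.empty((len(centers), 8), dtype=np.float64)
    for start in range(0, len(centers), batch):
        cb = centers[start : start + batch]
        nb = len(cb)
        vals = q[cb[:, 0, None] + offsets[None, :, 0], cb[:, 1, None] + offsets[None, :, 1]]
        sum_hist = np.zeros((nb, n_bins), dtype=np.float64)
        diff_hist = np.zeros((nb, n_bins), dtype=np.float64)
        row = (np.arange(nb) * n_bins)[:, None]
        total = 0
        for ai, aj in pair_idx:
            a = vals[:, ai]
            b = vals[:, aj]
            s = a + b
            d = a - b + (levels - 1)
            sum_hist += np.bincount((row + s).ravel(), minlength=nb * n_bins).reshape(nb, n_bins)
            diff_hist += np.bincount((row + d).ravel(), minlength=nb * n_bins).reshape(nb, n_bins)
            total += len(ai)
        sum_hist /= total
        diff_hist /= total
        out[start : start + nb] = _features_from_hist_batch(sum_hist, diff_hist, levels, vmin, step)
    return out


def unser_features(
    plane: np.ndarray,
    center: tuple[int, int],
    radius_px: int,
    displacement: tuple[int, int] | None = None,
    levels: int = DEFAULT_QUANT_LEVELS,
    plane_id: str = "",
    step: float | None = None,
) -> UnserFeatures:
    """Unser features of the circular neighborhood around one center (y, x).

    ``displacement=None`` (default) pools the four unit displacements at 0,
    45, 90 and 135 degrees, matching the rotation-robustness aim of the
    descriptors; a single displacement can be forced for analysis.
    """
    disp = UNIT_DISPLACEMENTS if displacement is None else (tuple(displacement),)
    row = unser_feature_grid(plane, np.array([center]), radius_px, disp, levels, step=step)[0]
    return UnserFeatures(*row, radius_px=radius_px, plane=plane_id)


def valid_centers(
    shape: tuple[int, int],
    centers: np.ndarray,
    radius_px: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean selector of centers whose full neighborhood lies in-image
    (and inside ``mask`` when given; such centers are skipped, not padded)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=np.int64))
    r = radius_px
    H, W = shape
    ok = (
        (centers[:, 0] >= r)
        & (centers[:, 1] >= r)
        & (centers[:, 0] < H - r)
        & (centers[:, 1] < W - r)
    )
    if mask is not None:
        offsets = disk_offsets(radius_px)
        idx = np.where(ok)[0]
        if idx.size:
            cb = centers[idx]
            inside = mask[
                cb[:, 0, None] + offsets[None, :, 0], cb[:, 1, None] + offsets[None, :, 1]
            ].all(axis=1)
            ok[idx] &= inside
    return ok


def lbp_code_image(
    plane: np.ndarray,
    n_points: int,
    radius_px: float,
    variant: str = "uniform_rotation_invariant",
) -> tuple[np.ndarray, int]:
    """Per-pixel LBP codes and the number of code bins for the variant."""
    if n_points < 4:
        raise ConfigError(f"n_points must be >= 4, got {n_points}")
    try:
        method = _LBP_METHOD[variant]
    except KeyError:
        raise ConfigError(f"unknown LBP variant {variant!r}") from None
    import warnings

    with warnings.catch_warnings():
        # float planes are intended here; codes feed histograms/threshold maps
        warnings.filterwarnings("ignore", message=".*floating-point images.*")
        codes = local_binary_pattern(
            np.asarray(plane, dtype=np.float64), n_points, radius_px, method
        )
    if variant == "uniform_rotation_invariant":
        n_bins = n_points + 2
    elif variant == "uniform":
        n_bins = n_points * (n_points - 1) + 3
    else:
        n_bins = 2**n_points
    return codes.astype(np.int64), n_bins


def lbp_descriptor(
    plane: np.ndarray,
    center: tuple[int, int],
    radius_px: int,
    n_points: int = 16,
    variant: str = "uniform_rotation_invariant",
    sampling_radius: float | None = None,
) -> LbpDescriptor:
    """Normalized LBP code histogram over the circular Omega around ``center``.

    ``sampling_radius`` is the circle the codes themselves sample on
    (default: same as the neighborhood radius, capped so the sampling
    circle of edge pixels stays in-image).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if sampling_radius is None:
        sampling_radius = radius_px
    codes, n_bins = lbp_code_image(plane, n_points, sampling_radius, variant)
    offsets = disk_offsets(radius_px)
    cy, cx = center
    H, W = plane.shape
    r = radius_px
    margin = int(np.ceil(sampling_radius))
    if cy - r < margin or cx - r < margin or cy + r >= H - margin or cx + r >= W - margin:
        raise ValidationError("sampling circle exits the plane for this center")
    vals = codes[cy + offsets[:, 0], cx + offsets[:, 1]]
    hist = np.bincount(vals, minlength=n_bins).astype(np.float64)
    hist /= hist.sum()
    return LbpDescriptor(hist, radius_px=radius_px, n_points=n_points, variant=variant)
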