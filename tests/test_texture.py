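"""Unser sum/difference-histogram features and LBP descriptors."""

import numpy as np
import pytest

from ki67hotspot.errors import ConfigError, ValidationError
from ki67hotspot.texture import (
    UNIT_DISPLACEMENTS,
    disk_offsets,
    lbp_code_image,
    lbp_descriptor,
    quantize_plane,
    unser_features,
    valid_centers,
)


def unser_bruteforce(plane, center, radius, displacements, levels=64, step=None):
    """Pair-enumeration oracle: loops over every in-neighborhood pixel pair."""
    q, vmin, step = quantize_plane(plane, levels, step=step)
    cy, cx = center
    inside = {
        (cy + dy, cx + dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    }
    sums, diffs = [], []
    for (y, x) in inside:
        for (dy, dx) in displacements:
            if (y + dy, x + dx) in inside:
                a, b = int(q[y, x]), int(q[y + dy, x + dx])
                sums.append(a + b)
                diffs.append(a - b)
    sums = np.asarray(sums)
    diffs = np.asarray(diffs)
    n = len(sums)
    ps = {s: (sums == s).sum() / n for s in set(sums)}
    pd = {d: (diffs == d).sum() / n for d in set(diffs)}
    mu_s = sum(s * p for s, p in ps.items())
    m2s = sum((s - mu_s) ** 2 * p for s, p in ps.items())
    m3s = sum((s - mu_s) ** 3 * p for s, p in ps.items())
    m4s = sum((s - mu_s) ** 4 * p for s, p in ps.items())
    m2d = sum(d * d * p for d, p in pd.items())
    return {
        "mean": vmin + step * mu_s / 2,
        "variance": 0.5 * (m2s + m2d),
        "homogeneity": sum(p / (1 + d * d) for d, p in pd.items()),
        "contrast": m2d,
        "energy": sum(p * p for p in ps.values()) * sum(p * p for p in pd.values()),
        "correlation": 0.5 * (m2s - m2d),
        "cluster_shade": m3s,
        "cluster_prominence": m4s,
    }


class TestUnser:
    def test_constant_region_degenerate_histograms(self):
        plane = np.full((32, 32), 77.0)
        f = unser_features(plane, (16, 16), radius_px=8)
        assert f.mean == pytest.approx(77.0)
        assert f.variance == 0 and f.contrast == 0
        assert f.energy == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(1.0)

    def test_checkerboard_equals_pair_enumeration_oracle(self):
        yy, xx = np.mgrid[0:24, 0:24]
        plane = ((yy + xx) % 2) * 255.0
        got = unser_features(plane, (12, 12), radius_px=8, displacement=(0, 1))
        want = unser_bruteforce(plane, (12, 12), 8, [(0, 1)])
        for name, val in want.items():
            assert getattr(got, name) == pytest.approx(val, rel=1e-9), name

    def test_random_patch_equals_oracle_all_displacements(self, rng):
        plane = rng.integers(0, 256, size=(28, 28)).astype(float)
        got = unser_features(plane, (14, 14), radius_px=9)
        want = unser_bruteforce(plane, (14, 14), 9, UNIT_DISPLACEMENTS)
        for name, val in want.items():
            assert getattr(got, name) == pytest.approx(val, rel=1e-9), name

    def test_intensity_offset_shifts_only_mean(self, rng):
        plane = rng.integers(0, 200, size=(26, 26)).astype(float)
        base = unser_features(plane, (13, 13), radius_px=8)
        shifted = unser_features(plane + 31.5, (13, 13), radius_px=8)
        assert shifted.mean == pytest.approx(base.mean + 31.5)
        for name in ("variance", "homogeneity", "contrast", "energy", "correlation"):
            assert getattr(shifted, name) == pytest.approx(getattr(base, name)), name

    def test_neighborhood_exits_image_rejected(self):
        with pytest.raises(ValidationError):
            unser_features(np.zeros((16, 16)), (2, 2), radius_px=8)

    def test_independent_train_test_radii(self, rng):
        """The extraction API accepts a different radius per call, so a larger
        training neighborhood can feed the same classifier."""
        plane = rng.integers(0, 256, size=(40, 40)).astype(float)
        f10 = unser_features(plane, (20, 20), radius_px=10)
        f12 = unser_features(plane, (20, 20), radius_px=12)
        assert f10.radius_px == 10 and f12.radius_px == 12


def _bilinear(img, r, c):
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1 = min(r0 + 1, img.shape[0] - 1)
    c1 = min(c0 + 1, img.shape[1] - 1)
    dr, dc = r - r0, c - c0
    top = (1 - dc) * img[r0, c0] + dc * img[r0, c1]
    bot = (1 - dc) * img[r1, c0] + dc * img[r1, c1]
    return (1 - dr) * top + dr * bot


def lbp_naive(img, P, R, variant):
    """Per-pixel loop oracle replicating circular sampling and code mapping."""
    H, W = img.shape
    out = np.zeros((H, W), np.int64)
    rr = -R * np.sin(2 * np.pi * np.arange(P) / P)
    cc = R * np.cos(2 * np.pi * np.arange(P) / P)
    rr = np.round(rr, 8)
    cc = np.round(cc, 8)
    m = int(np.ceil(R))
    for y in range(m, H - m):
        for x in range(m, W - m):
            bits = [
                1 if _bilinear(img, y + rr[i], x + cc[i]) - img[y, x] >= 0 else 0
                for i in range(P)
            ]
            trans = sum(bits[i] != bits[(i + 1) % P] for i in range(P))
            if variant == "uniform_rotation_invariant":
                out[y, x] = sum(bits) if trans <= 2 else P + 1
            elif variant == "rotation_invariant":
                codes = [
                    sum(bits[(i + k) % P] << i for i in range(P)) for k in range(P)
                ]
                out[y, x] = min(codes)
            else:
                raise ValueError(variant)
    return out


class TestLbp:
    def test_constant_image_all_bits_set(self):
        plane = np.full((20, 20), 9.0)
        d = lbp_descriptor(plane, (10, 10), radius_px=4, n_points=8,
                           sampling_radius=1.0)
        # all-ones pattern -> uniform code == n_points
        assert d.histogram[8] == pytest.approx(1.0)
        assert d.histogram.sum() == pytest.approx(1.0, abs=1e-9)

    def test_histogram_bin_count_per_variant(self, rng):
        plane = rng.integers(0, 256, size=(40, 40)).astype(float)
        for variant, bins in [
            ("uniform_rotation_invariant", 10),
            ("uniform", 8 * 7 + 3),
            ("rotation_invariant", 256),
        ]:
            d = lbp_descriptor(plane, (20, 20), radius_px=6, n_points=8,
                               variant=variant, sampling_radius=2.0)
            assert len(d.histogram) == bins
            assert d.histogram.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance_under_quarter_turns(self, rng):
        plane = rng.integers(0, 256, size=(33, 33)).astype(float)
        c = 16
        d0 = lbp_descriptor(plane, (c, c), radius_px=8, n_points=8,
                            sampling_radius=2.0)
        d90 = lbp_descriptor(np.rot90(plane).copy(), (c, c), radius_px=8,
                             n_points=8, sampling_radius=2.0)
        np.testing.assert_allclose(d0.histogram, d90.histogram, atol=1e-12)

    @pytest.mark.parametrize("variant", ["uniform_rotation_invariant", "rotation_invariant"])
    def test_codes_equal_naive_loop_oracle(self, rng, variant):
        img = rng.integers(0, 256, size=(16, 16)).astype(float)
        codes, _ = lbp_code_image(img, 8, 1.0, variant)
        want = lbp_naive(img, 8, 1.0, variant)
        np.testing.assert_array_equal(codes[2:-2, 2:-2], want[2:-2, 2:-2])

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigError):
            lbp_code_image(np.zeros((8, 8)), 3, 1.0)

    def test_sampling_circle_must_fit(self):
        with pytest.raises(ValidationError):
            lbp_descriptor(np.zeros((12, 12)), (2, 2), radius_px=4, n_points=8)


def test_valid_centers_respects_mask():
    mask = np.zeros((30, 30), bool)
    mask[5:25, 5:25] = True
    centers = np.array([(15, 15), (6, 6), (2, 2)])
    ok = valid_centers((30, 30), centers, radius_px=4, mask=mask)
    assert ok.tolist() == [True, False, False]


def test_disk_offsets_radius_bound():
    offs = disk_offsets(5)
    assert (offs**2).sum(axis=1).max() <= 25
    assert len(offs) == ((np.mgrid[-5:6, -5:6][0] ** 2 + np.mgrid[-5:6, -5:6][1] ** 2) <= 25).sum()
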