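"""Color-artifact cut-off and h-minima cell extraction."""

import numpy as np
import pytest

from ki67hotspot import cells
from ki67hotspot.cells import (
    color_artifact_cutoff,
    extended_minima,
    extract_negative_cells,
    extract_positive_cells,
    background_region,
    ki67_index,
)
from ki67hotspot.errors import ConfigError, ValidationError


def reconstruction_oracle(seed, mask_img):
    """Brute-force grayscale erosion reconstruction (8-connected)."""
    rec = seed.copy()
    while True:
        prev = rec.copy()
        eroded = prev.copy()
        H, W = prev.shape
        for y in range(H):
            for x in range(W):
                lo = prev[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2].min()
                eroded[y, x] = lo
        rec = np.maximum(eroded, mask_img)
        if np.array_equal(rec, prev):
            return rec


def regional_minima_oracle(img):
    """A pixel belongs to a regional minimum iff its connected plateau has
    no strictly lower 8-neighbor."""
    H, W = img.shape
    out = np.ones((H, W), bool)
    # iteratively clear plateaus adjacent to lower values
    changed = True
    for y in range(H):
        for x in range(W):
            lo = img[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2].min()
            if lo < img[y, x]:
                out[y, x] = False
    changed = True
    while changed:
        changed = False
        for y in range(H):
            for x in range(W):
                if out[y, x]:
                    win = out[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
                    vals = img[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
                    if np.any((vals == img[y, x]) & ~win):
                        out[y, x] = False
                        changed = True
    return out


def _wells_plane(n_wells=12, depth=60.0, bg=200.0, size=64):
    plane = np.full((size, size), bg)
    centers = []
    step = size // 4
    for i in range(3):
        for j in range(4):
            cy, cx = step // 2 + i * 21, step // 2 + j * 15
            yy, xx = np.mgrid[-2:3, -2:3]
            disk = yy**2 + xx**2 <= 4
            plane[cy - 2 : cy + 3, cx - 2 : cx + 3][disk] = bg - depth
            centers.append((cx, cy))
    return plane, centers[:n_wells]


class TestArtifactCutoff:
    def test_uniform_region_unchanged_and_unflagged(self):
        lum = np.full((20, 20), 80.0)
        mask = np.ones((20, 20), bool)
        adjusted, flag = color_artifact_cutoff(lum, mask)
        np.testing.assert_array_equal(adjusted, lum)
        assert not flag

    def test_dark_outliers_all_removed_and_flagged(self, rng):
        lum = np.r_[rng.uniform(70, 95, 10_000), np.zeros(100)]
        lum = lum.reshape(101, 100)
        mask = np.ones_like(lum, bool)
        adjusted, flag = color_artifact_cutoff(lum, mask)
        p5 = np.percentile(lum, 5)
        assert flag
        assert (adjusted >= p5 - 1e-12).all()
        # the 100 zero-valued outliers all fell inside the removed 5%
        assert np.allclose(adjusted[lum == 0], p5)

    def test_removed_fraction_is_five_percent(self, rng):
        lum = rng.normal(70, 8, size=(120, 110))
        mask = np.ones_like(lum, bool)
        adjusted, _ = color_artifact_cutoff(lum, mask)
        changed = (adjusted != lum).sum()
        n = lum.size
        assert abs(changed / n - 0.05) <= 1.5 / n  # pixel quantization

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            color_artifact_cutoff(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestExtendedMinima:
    def test_twelve_wells_recovered(self):
        plane, centers = _wells_plane()
        markers = extract_positive_cells(plane, np.ones_like(plane, bool), h=30)
        assert markers.count == 12
        got = {tuple(c) for c in markers.centroids}
        for (cx, cy) in centers:
            assert any(abs(gx - cx) <= 1 and abs(gy - cy) <= 1 for gx, gy in got)

    def test_h_deeper_than_any_well_finds_nothing(self):
        plane, _ = _wells_plane(depth=60.0)
        markers = extract_positive_cells(plane, np.ones_like(plane, bool), h=80)
        assert markers.count == 0

    def test_shallow_saddle_merges_two_wells(self):
        plane = np.full((32, 32), 200.0)
        plane[15, 5:15] = 140.0
        plane[15, 17:27] = 140.0
        plane[15, 15:17] = 155.0  # barrier 15 above the floors, < h
        m = extract_positive_cells(plane, np.ones_like(plane, bool), h=30)
        assert m.count == 1

    def test_high_saddle_keeps_wells_separate(self):
        plane = np.full((32, 32), 200.0)
        plane[15, 5:15] = 140.0
        plane[15, 17:27] = 140.0
        plane[15, 15:17] = 185.0  # barrier 45 above the floors, > h
        m = extract_positive_cells(plane, np.ones_like(plane, bool), h=30)
        assert m.count == 2

    def test_equals_reconstruction_oracle(self, rng):

        plane = np.round(rng.uniform(0, 100, size=(24, 24)))
        mask = np.ones((24, 24), bool)
        h = 15.0
        got = extended_minima(plane, mask, h)
        rec = reconstruction_oracle(plane + h, plane)
        want = regional_minima_oracle(rec)
        if want.all():
            want = np.zeros_like(want)
        np.testing.assert_array_equal(got, want)

    def test_count_monotone_non_increasing_in_h(self, rng):
        plane = np.round(rng.uniform(0, 100, size=(48, 48)))
        mask = np.ones((48, 48), bool)
        counts = [
            extract_positive_cells(plane, mask, h=h).count for h in (5, 10, 20, 40, 80)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_complement_identity(self):
        plane, _ = _wells_plane()
        mask = np.ones_like(plane, bool)
        cells_region = extended_minima(plane, mask, 30)
        bg = background_region(plane, mask, 30)
        assert not (cells_region & bg).any()
        np.testing.assert_array_equal(cells_region | bg, mask)

    def test_non_positive_h_rejected(self):
        with pytest.raises(ConfigError):
            extract_positive_cells(np.zeros((8, 8)), np.ones((8, 8), bool), h=0)

    def test_centroid_rounding_ties_toward_smaller(self):
        # a 2x2 component has center of mass (0.5, 0.5) -> rounds to (0, 0)
        plane = np.full((8, 8), 100.0)
        plane[3:5, 3:5] = 10.0
        m = extract_positive_cells(plane, np.ones_like(plane, bool), h=50)
        assert m.count == 1
        assert tuple(m.centroids[0]) == (3, 3)


class TestNegativePass:
    def test_positive_components_not_double_counted(self):
        plane = np.full((40, 40), 100.0)
        plane[10, 10] = 10.0  # shared well on both planes
        plane[30, 30] = 10.0
        pos_mask = np.zeros((40, 40), bool)
        pos_mask[10, 10] = True
        m = extract_negative_cells(plane, np.ones_like(plane, bool), h=50,
                                   exclude_mask=pos_mask)
        assert m.count == 1
        assert tuple(m.centroids[0]) == (30, 30)

    def test_slide_level_recovery(self, clean_slide, clean_planes, clean_tissue_mask):
        _, gt = clean_slide
        pos = extract_positive_cells(clean_planes["L"], clean_tissue_mask, h=20)
        neg = extract_negative_cells(
            clean_planes["hematoxylin"], clean_tissue_mask, h=8,
            exclude_mask=pos.cell_mask,
        )
        assert abs(pos.count - gt.achieved_pos) / gt.achieved_pos < 0.1
        assert abs(neg.count - gt.achieved_neg) / gt.achieved_neg < 0.1


class TestKi67Index:
    @pytest.mark.parametrize("pos,neg,expected", [(50, 50, 50.0), (0, 100, 0.0), (30, 70, 30.0)])
    def test_ratio(self, pos, neg, expected):
        assert ki67_index(pos, neg) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            ki67_index(0, 0)
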