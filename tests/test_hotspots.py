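"""Density map, penalty function, size rules and gradual extinction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ki67hotspot.errors import ConfigError, ValidationError
from ki67hotspot.hotspots import (
    DensityMap,
    PenaltyState,
    compactness_adjusted_rho,
    density_map,
    max_hotspot_count,
    penalty,
    select_hotspots,
)
from ki67hotspot.slide_io import FovGeometry


def _fov(w=32, h=24):
    return FovGeometry(width_px=w, height_px=h, um_per_px=3.1116)


def _dmap(counts, valid=None, fov=None, stride=(16, 12)):
    counts = np.asarray(counts)
    return DensityMap(
        counts=counts,
        valid=np.ones_like(counts, bool) if valid is None else valid,
        origin_xy=(0, 0),
        stride_xy=stride,
        fov=fov or _fov(),
    )


def greedy_extinction_oracle(counts, rho, n_max, fov_w, stride):
    """From-scratch greedy loop recomputing every penalty each iteration."""
    ny, nx = counts.shape
    centers = {
        (iy, ix): (ix * stride[0] + fov_w / 2, iy * stride[1] + 24 / 2)
        for iy in range(ny)
        for ix in range(nx)
    }
    selected = []
    order = []
    while len(order) < n_max:
        best, best_key = None, None
        for iy in range(ny):
            for ix in range(nx):
                if (iy, ix) in order or counts[iy, ix] <= 0:
                    continue
                cx, cy = centers[(iy, ix)]
                pen = 1.0
                for (sx, sy) in selected:
                    d = np.hypot(cx - sx, cy - sy) / fov_w
                    pen -= rho * d**-0.5
                pen = max(pen, 0.0)
                key = (counts[iy, ix] * pen, counts[iy, ix], -(iy * nx + ix))
                if best is None or key > best:
                    best, best_key = key, (iy, ix)
        if best is None:
            break
        order.append(best_key)
        selected.append(centers[best_key])
    return order


class TestDensityMap:
    def test_single_centroid_counted_once_per_covering_window(self):
        mask = np.ones((48, 64), bool)
        dm = density_map(np.array([[10, 10]]), mask, _fov(), stride_xy=(16, 12))
        assert dm.counts.max() == 1
        assert dm.counts[0, 0] == 1  # window [0,32)x[0,24) covers (10,10)
        assert dm.counts[dm.counts > 0].sum() >= 1

    def test_partition_conservation(self, rng):
        mask = np.ones((96, 128), bool)
        pts = np.c_[rng.integers(0, 128, 500), rng.integers(0, 96, 500)]
        dm = density_map(pts, mask, _fov(), stride_xy=(32, 24))  # non-overlapping tiling
        assert dm.counts.sum() == 500

    def test_equals_bruteforce_recount(self, rng):
        mask = np.ones((72, 96), bool)
        pts = np.c_[rng.integers(0, 96, 200), rng.integers(0, 72, 200)]
        dm = density_map(pts, mask, _fov(), stride_xy=(16, 12))
        for iy in range(dm.counts.shape[0]):
            for ix in range(dm.counts.shape[1]):
                x0, y0, w, h = dm.rect(iy, ix)
                want = (
                    (pts[:, 0] >= x0) & (pts[:, 0] < x0 + w)
                    & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + h)
                ).sum()
                assert dm.counts[iy, ix] == want

    def test_low_coverage_candidates_invalid(self):
        mask = np.zeros((48, 64), bool)
        mask[:, :16] = True  # covers half of the first window column at most
        dm = density_map(np.empty((0, 2)), mask, _fov(), min_coverage=0.9)
        assert not dm.valid.any()

    def test_fov_larger_than_image_rejected(self):
        with pytest.raises(ValidationError):
            density_map(np.empty((0, 2)), np.ones((16, 16), bool), _fov(32, 24))


class TestPenalty:
    def test_empty_selection_gives_one(self):
        state = PenaltyState(rho=0.7, fov_width_px=128)
        assert penalty((999.0, -3.0), state) == 1.0

    def test_single_field_at_distance_four(self):
        state = PenaltyState(rho=0.3, fov_width_px=128, selected_xy=[(0.0, 0.0)])
        assert penalty((4 * 128.0, 0.0), state) == pytest.approx(1 - 0.3 / 4**0.5)

    @given(
        st.lists(
            st.tuples(st.floats(-500, 500), st.floats(-500, 500)),
            min_size=1,
            max_size=6,
        )
    )
    def test_equals_scalar_loop(self, selected):
        cand = (700.0, 800.0)
        if any(np.hypot(cand[0] - x, cand[1] - y) == 0 for x, y in selected):
            return
        state = PenaltyState(rho=0.25, fov_width_px=100.0, selected_xy=list(selected))
        total = sum(
            (np.hypot(cand[0] - x, cand[1] - y) / 100.0) ** -0.5 for x, y in selected
        )
        assert penalty(cand, state) == pytest.approx(max(1 - 0.25 * total, 0.0))

    def test_zero_distance_rejected(self):
        state = PenaltyState(rho=0.3, fov_width_px=128, selected_xy=[(5.0, 5.0)])
        with pytest.raises(ValidationError):
            penalty((5.0, 5.0), state)


class TestSizeRules:
    @pytest.mark.parametrize("area,expected", [(500, 20), (250, 10), (0, 0), (125, 5), (800, 20)])
    def test_max_count(self, area, expected):
        assert max_hotspot_count(area) == expected

    def test_negative_area_rejected(self):
        with pytest.raises(ValidationError):
            max_hotspot_count(-1)

    @pytest.mark.parametrize(
        "area,radius,factor",
        [(200, 10, 1.0), (50, 10, 0.5), (200, 3, 0.5), (25, 3, 0.25)],
    )
    def test_compactness_reduction(self, area, radius, factor):
        assert compactness_adjusted_rho(0.3, area, radius) == pytest.approx(0.3 * factor)


class TestSelection:
    def test_single_candidate(self):
        dm = _dmap([[10]])
        out = select_hotspots(dm, rho=0.3, n_max=5)
        assert len(out) == 1
        assert out.fields[0].raw_count == 10
        assert out.fields[0].penalized_score == 10.0

    def test_rho_zero_reduces_to_greedy_topk(self, rng):
        counts = rng.integers(0, 50, size=(6, 8))
        dm = _dmap(counts)
        out = select_hotspots(dm, rho=0.0, n_max=10)
        got = [f.raw_count for f in out.fields]
        want = sorted(counts.ravel(), reverse=True)[:10]
        assert got == list(want)

    def test_two_equal_clusters_alternate(self):
        counts = np.zeros((1, 11), int)
        counts[0, 0] = 30
        counts[0, 10] = 30
        dm = _dmap(counts, stride=(64, 48))
        out = select_hotspots(dm, rho=0.3, n_max=4)
        cols = [f.rect_working[0] // 64 for f in out.fields]
        assert sorted(cols[:2]) == [0, 10]  # one from each far-apart cluster first

    def test_dominant_cluster_retains_all_selections(self):
        counts = np.zeros((1, 12), int)
        counts[0, 0:3] = 100
        counts[0, 9:12] = 1
        dm = _dmap(counts, stride=(64, 48))
        out = select_hotspots(dm, rho=0.3, n_max=3)
        assert all(f.rect_working[0] // 64 <= 2 for f in out.fields)
        assert all(f.raw_count == 100 for f in out.fields)

    def test_matches_greedy_loop_oracle(self, rng):
        counts = rng.integers(0, 40, size=(5, 7))
        dm = _dmap(counts, stride=(16, 12))
        out = select_hotspots(dm, rho=0.2, n_max=8)
        want = greedy_extinction_oracle(counts, 0.2, 8, dm.fov.width_px, (16, 12))
        got = [
            ((f.rect_working[1]) // 12, (f.rect_working[0]) // 16) for f in out.fields
        ]
        assert got == want

    def test_scores_non_increasing(self, rng):
        counts = rng.integers(1, 30, size=(6, 6))
        out = select_hotspots(_dmap(counts), rho=0.25, n_max=12)
        scores = [f.penalized_score for f in out.fields]
        assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_fields_are_distinct_grid_positions(self, rng):
        counts = rng.integers(1, 30, size=(5, 5))
        out = select_hotspots(_dmap(counts), rho=0.1, n_max=25)
        rects = {f.rect_working for f in out.fields}
        assert len(rects) == len(out.fields)

    def test_no_positive_candidates_warns_and_returns_empty(self):
        dm = _dmap(np.zeros((3, 3), int))
        with pytest.warns(UserWarning):
            out = select_hotspots(dm, rho=0.3, n_max=5)
        assert len(out) == 0

    def test_negative_rho_rejected(self):
        with pytest.raises(ConfigError):
            select_hotspots(_dmap([[1]]), rho=-0.1)

    def test_level0_coordinates_scale_with_downsample(self):
        dm = _dmap([[5]])
        out = select_hotspots(dm, rho=0.0, n_max=1, downsample=8.0)
        x0, y0, w, h = out.fields[0].rect_level0
        assert (w, h) == (8 * dm.fov.width_px, 8 * dm.fov.height_px)
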