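"""Terrain model: lowest-points rule, chessboard grid, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocloud import PointCloud, build_dtm, compare_dtm, normalize_heights, tile_ground_elevation


class TestTileGroundElevation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1.0] * 17 + [2.0] * 3, 1.0),        # k = ceil(0.15*20) = 3, all lowest 1.0
            ([5.0] * 8, 5.0),
            (list(range(10)), 0.5),                # k = ceil(1.5) = 2 -> mean(0, 1)
            ([7.25], 7.25),                        # single point, k = 1
        ],
    )
    def test_hand_computed_means(self, values, expected):
        assert tile_ground_elevation(values) == pytest.approx(expected)

    def test_empty_tile_signals(self):
        with pytest.raises(ValueError, match="empty tile"):
            tile_ground_elevation([])

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            tile_ground_elevation([1.0], fraction=0.0)
        assert tile_ground_elevation([3.0, 1.0], fraction=1.0) == pytest.approx(2.0)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50), st.floats(-100, 0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_adding_lower_point(self, zs, delta):
        """Adding a point at or below the current estimate never raises it."""
        before = tile_ground_elevation(zs)
        after = tile_ground_elevation(zs + [before + delta])
        assert after <= before + 1e-9

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_mean(self, zs):
        assert tile_ground_elevation(zs) <= np.mean(zs) + 1e-9


class TestBuildDtm:
    def test_flat_plane_every_tile(self, rng):
        xyz = np.column_stack([rng.uniform(0, 10, 2000), rng.uniform(0, 10, 2000),
                               np.full(2000, 7.0)])
        dtm = build_dtm(PointCloud(xyz))
        np.testing.assert_allclose(dtm.elevations, 7.0)
        assert not dtm.fill_mask.any()

    def test_sloped_plane_tile_rmse(self, rng):
        n = 100 * 400  # 100 pts/m2 over 20 x 20 m
        x = rng.uniform(0, 20, n)
        y = rng.uniform(0, 20, n)
        z = 2.0 + 0.01 * x
        dtm = build_dtm(PointCloud(np.column_stack([x, y, z])))
        cx, cy = dtm.tile_centers()
        truth = 2.0 + 0.01 * cx[None, :] + 0.0 * cy[:, None]
        rmse = np.sqrt(np.mean((dtm.elevations - truth) ** 2))
        assert rmse <= 0.05

    def test_noisy_flat_terrain_recovery(self, rng):
        """Tree-free terrain with 2 cm Gaussian noise: tile-to-tile scatter
        about the (datum-shifted) truth is far below 3 cm, and the datum
        shift itself equals the analytic mean of the lowest 15% of a
        normal, -1.554 sigma."""
        n = 500 * 400
        xyz = np.column_stack([rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                               5.0 + rng.normal(0, 0.02, n)])
        dtm = build_dtm(PointCloud(xyz))
        bias = dtm.elevations.mean() - 5.0
        scatter = dtm.elevations.std()
        assert scatter <= 0.03
        assert bias == pytest.approx(-1.554 * 0.02, abs=0.003)

    def test_single_point_cloud(self):
        dtm = build_dtm(PointCloud([[3.0, 3.0, 9.0]]))
        assert dtm.shape == (1, 1)
        assert dtm.elevations[0, 0] == 9.0

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_dtm(PointCloud(np.zeros((0, 3))))

    def test_point_order_invariance(self, rng):
        xyz = np.column_stack([rng.uniform(0, 12, 1000), rng.uniform(0, 12, 1000),
                               rng.uniform(0, 2, 1000)])
        a = build_dtm(PointCloud(xyz))
        b = build_dtm(PointCloud(xyz[rng.permutation(1000)]))
        assert a.origin == b.origin
        np.testing.assert_array_equal(a.elevations, b.elevations)

    def test_elevation_bounds_within_cloud_range(self, rng):
        xyz = np.column_stack([rng.uniform(0, 10, 500), rng.uniform(0, 10, 500),
                               rng.uniform(3, 8, 500)])
        dtm = build_dtm(PointCloud(xyz))
        assert dtm.elevations.min() >= xyz[:, 2].min() - 1e-9
        assert dtm.elevations.max() <= xyz[:, 2].max() + 1e-9

    def test_empty_tiles_filled_from_nearest_and_flagged(self):
        # two clusters 10 m apart leave empty tiles between them
        left = np.column_stack([np.full(20, 0.5), np.linspace(0, 1.9, 20), np.full(20, 4.0)])
        right = np.column_stack([np.full(20, 12.5), np.linspace(0, 1.9, 20), np.full(20, 6.0)])
        dtm = build_dtm(PointCloud(np.vstack([left, right])))
        assert dtm.fill_mask.any()
        filled = dtm.elevations[dtm.fill_mask]
        assert set(np.round(filled, 6)) <= {4.0, 6.0}
        # nearest rule: tiles adjacent to the left cluster take its value
        assert dtm.elevations[0, 1] == pytest.approx(4.0)

    def test_grid_origin_floor_aligned(self):
        dtm = build_dtm(PointCloud([[3.7, 5.1, 1.0]]), tile_size=2.0)
        assert dtm.origin == (2.0, 4.0)


class TestNormalizeHeights:
    def test_height_above_tile(self):
        pc = PointCloud([[1.0, 1.0, 10.0]])
        dtm = build_dtm(PointCloud([[1.0, 1.0, 9.7]]))
        out = normalize_heights(pc, dtm)
        assert out.height_above_terrain[0] == pytest.approx(0.3)

    def test_points_on_terrain_are_near_zero(self, rng):
        xyz = np.column_stack([rng.uniform(0, 10, 3000), rng.uniform(0, 10, 3000),
                               np.full(3000, 2.5)])
        pc = PointCloud(xyz)
        out = normalize_heights(pc, build_dtm(pc))
        assert np.abs(out.height_above_terrain).max() <= 1e-9

    def test_point_outside_extent_named(self):
        dtm = build_dtm(PointCloud([[1.0, 1.0, 0.0]]))
        with pytest.raises(ValueError, match=r"\(50\.0, 50\.0\)"):
            normalize_heights(PointCloud([[50.0, 50.0, 1.0]]), dtm)

    def test_negative_heights_kept(self):
        base = np.column_stack([np.linspace(0, 1.9, 50), np.linspace(0, 1.9, 50),
                                np.full(50, 5.0)])
        pc = PointCloud(np.vstack([base, [[1.0, 1.0, 4.9]]]))
        out = normalize_heights(pc, build_dtm(pc))
        assert out.height_above_terrain.min() < 0


class TestCompareDtm:
    @staticmethod
    def _dtm(rng):
        n = 40000
        x = rng.uniform(0, 100, n)
        y = rng.uniform(0, 100, n)
        z = 10.0 + 0.01 * x  # 1 m relief over the field
        return build_dtm(PointCloud(np.column_stack([x, y, z])))

    def test_exact_reference(self, rng):
        dtm = self._dtm(rng)
        xs = rng.uniform(0, 100, 30)
        ys = rng.uniform(0, 100, 30)
        refs = dtm.elevation_at(xs, ys)
        stats = compare_dtm(dtm, np.column_stack([xs, ys, refs]), grid_spacing=None)
        assert stats.r_squared == pytest.approx(1.0)
        assert stats.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_reference(self, rng):
        """A datum shift leaves R^2 = 1 and zero scatter about the fit;
        the bias shows up in the intercept."""
        dtm = self._dtm(rng)
        xs = rng.uniform(0, 100, 30)
        ys = rng.uniform(0, 100, 30)
        refs = dtm.elevation_at(xs, ys) + 0.5
        stats = compare_dtm(dtm, np.column_stack([xs, ys, refs]), grid_spacing=None)
        assert stats.r_squared == pytest.approx(1.0)
        assert stats.rmse_fit == pytest.approx(0.0, abs=1e-10)
        assert stats.intercept == pytest.approx(-0.5, abs=1e-6)

    def test_noisy_20m_grid_sampling(self, rng):
        dtm = self._dtm(rng)
        gx, gy = np.meshgrid(np.arange(10, 100, 20), np.arange(10, 80, 20))
        xs, ys = gx.ravel(), gy.ravel()
        refs = dtm.elevation_at(xs, ys) + rng.normal(0, 0.03, xs.size)
        stats = compare_dtm(dtm, np.column_stack([xs, ys, refs]))
        assert stats.n == xs.size
        assert stats.r_squared >= 0.95

    def test_anomalous_samples_dismissed(self, rng):
        dtm = self._dtm(rng)
        xs = rng.uniform(0, 100, 10)
        ys = rng.uniform(0, 100, 10)
        refs = dtm.elevation_at(xs, ys)
        refs[0] += 50.0  # faulty reference point
        mask = np.zeros(10, dtype=bool)
        mask[0] = True
        stats = compare_dtm(dtm, np.column_stack([xs, ys, refs]),
                            grid_spacing=None, exclude_mask=mask)
        assert stats.n == 9
        assert stats.rmse == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_samples(self, rng):
        dtm = self._dtm(rng)
        with pytest.raises(ValueError, match="3"):
            compare_dtm(dtm, [[1, 1, 10.0], [2, 2, 10.0]], grid_spacing=None)
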