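"""Tree-point classification, crown delineation and seed assignment."""

import numpy as np
import pytest

from phenocloud import PointCloud
from phenocloud.detection import (
    OccupancyGrid,
    SeedTable,
    assign_crowns_to_seeds,
    classify_tree_points,
    counting_accuracy,
    delineate_crowns,
    generate_seed_grid,
    rasterize_occupancy,
)

from _oracles import brute_force_bins, count_components_union_find, nearest_seed_assignment


def _cloud_with_heights(heights):
    n = len(heights)
    xyz = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    return PointCloud(xyz, height_above_terrain=heights)


class TestClassify:
    def test_threshold_inclusive(self):
        out = classify_tree_points(_cloud_with_heights([0.29, 0.30, 0.31]))
        np.testing.assert_allclose(out.height_above_terrain, [0.30, 0.31])

    def test_all_below_gives_empty(self):
        assert len(classify_tree_points(_cloud_with_heights([0.1, 0.2]))) == 0

    def test_requires_normalized_heights(self):
        with pytest.raises(ValueError, match="normalize_heights"):
            classify_tree_points(PointCloud([[0, 0, 1]]))


class TestRasterize:
    def test_one_point_one_cell(self):
        occ = rasterize_occupancy(_cloud_with_heights([1.0]).select([0]))
        assert occ.occupied.sum() == 1

    def test_two_points_same_cell(self):
        pc = PointCloud([[0.51, 0.52, 1], [0.56, 0.53, 1]], height_above_terrain=[1, 1])
        assert rasterize_occupancy(pc).occupied.sum() == 1

    def test_matches_brute_force_binning(self, rng):
        xyz = np.column_stack([rng.uniform(0, 5, 1000), rng.uniform(0, 5, 1000), np.ones(1000)])
        pc = PointCloud(xyz, height_above_terrain=np.ones(1000))
        occ = rasterize_occupancy(pc, 0.1)
        expected = brute_force_bins(xyz[:, :2], occ.origin, 0.1)
        iy, ix = np.nonzero(occ.occupied)
        assert set(zip(ix.tolist(), iy.tolist())) == expected


def _grid(rows):
    """Occupancy grid from a list of 0/1 strings (top row first)."""
    arr = np.array([[c == "1" for c in row] for row in rows[::-1]], dtype=bool)
    return OccupancyGrid((0.0, 0.0), 0.1, arr)


class TestDelineate:
    def test_two_separated_blobs(self):
        cm = delineate_crowns(_grid([
            "1110011",
            "1110011",
            "1110011",
        ]), min_cells=1)
        assert len(cm.tree_ids) == 2

    def test_diagonal_adjacency_merges(self):
        cm = delineate_crowns(_grid([
            "1100",
            "1100",
            "0011",
            "0011",
        ]), min_cells=1)
        assert len(cm.tree_ids) == 1

    def test_single_cell(self):
        cm = delineate_crowns(_grid(["1"]), min_cells=1)
        assert cm.tree_ids == [1]
        assert not cm.interior_mask.any()

    def test_ring_interior_filled(self):
        cm = delineate_crowns(_grid([
            "11111",
            "10001",
            "10001",
            "11111",
        ]), min_cells=1)
        assert len(cm.tree_ids) == 1
        assert cm.interior_mask.sum() == 6
        assert (cm.labels[cm.interior_mask] == 1).all()

    def test_border_connected_background_not_filled(self):
        cm = delineate_crowns(_grid([
            "111",
            "101",
            "101",  # open channel to the bottom border
        ]), min_cells=1)
        assert not cm.interior_mask.any()
        # the channel cells (array rows 0-1 after the bottom-up flip) stay background
        assert (cm.labels[0, 1] == 0) and (cm.labels[1, 1] == 0)

    def test_min_cell_filter_drops_noise(self):
        cm = delineate_crowns(_grid([
            "110000000",
            "110000100",
        ]), min_cells=3)
        assert len(cm.tree_ids) == 1

    def test_label_count_matches_union_find(self, rng):
        for _ in range(25):
            occ = OccupancyGrid((0.0, 0.0), 0.1, rng.random((60, 60)) < 0.25)
            cm = delineate_crowns(occ, min_cells=1)
            assert len(cm.tree_ids) == count_components_union_find(occ.occupied)

    def test_interior_filling_preserves_label_count(self, rng):
        for _ in range(10):
            occ = OccupancyGrid((0.0, 0.0), 0.1, rng.random((50, 50)) < 0.4)
            cm = delineate_crowns(occ, min_cells=1)
            assert len(cm.tree_ids) == count_components_union_find(occ.occupied)
            # filled cells were background and are now labelled
            assert (cm.labels[cm.interior_mask] > 0).all()
            assert not (cm.interior_mask & occ.occupied).any()

    def test_empty_grid(self):
        cm = delineate_crowns(OccupancyGrid((0.0, 0.0), 0.1, np.zeros((4, 4), dtype=bool)))
        assert cm.tree_ids == []

    def test_deterministic_scan_order_labels(self):
        cm = delineate_crowns(_grid([
            "0011",
            "0011",
            "0000",  # keep the blobs clear of diagonal contact
            "1100",
            "1100",  # bottom-left blob occupies the first scan row
        ]), min_cells=1)
        assert cm.labels[0, 0] == 1
        assert cm.labels[4, 3] == 2


class TestSeedAssignment:
    def test_cell_within_radius_assigned(self):
        cm = delineate_crowns(_grid(["111"]), min_cells=1)
        seeds = SeedTable([9], [0.15], [0.05])
        out = assign_crowns_to_seeds(cm, seeds, radius=1.0)
        assert set(out.labels[out.labels > 0]) == {9}

    def test_cell_beyond_radius_unassigned(self):
        cm = delineate_crowns(_grid(["111"]), min_cells=1)
        seeds = SeedTable([3], [5.0, ], [5.0])
        out = assign_crowns_to_seeds(cm, seeds, radius=1.0)
        assert set(out.unassigned_ids) == set(np.unique(out.labels[out.labels > 0]))
        assert all(u > 3 for u in out.unassigned_ids)

    def test_merged_row_split_matches_brute_force(self):
        occ = OccupancyGrid((0.0, 0.0), 0.1, np.ones((1, 20), dtype=bool))
        cm = delineate_crowns(occ, min_cells=1)
        assert len(cm.tree_ids) == 1  # merged hedgerow component
        seeds = SeedTable([1, 2], [0.1, 1.85], [0.05, 0.05])
        out = assign_crowns_to_seeds(cm, seeds, radius=1.0)
        centers = occ.cell_centers()
        expected = nearest_seed_assignment(centers, seeds.tree_ids, seeds.xy, 1.0)
        got = out.labels[0, :]
        np.testing.assert_array_equal(got[: len(expected)], expected)

    def test_idempotent_and_seed_order_invariant(self, rng):
        occ = OccupancyGrid((0.0, 0.0), 0.1, rng.random((30, 30)) < 0.5)
        cm = delineate_crowns(occ, min_cells=1)
        seeds_a = SeedTable([1, 2, 3], [0.5, 1.5, 2.5], [1.5, 1.5, 1.5])
        seeds_b = SeedTable([3, 1, 2], [2.5, 0.5, 1.5], [1.5, 1.5, 1.5])
        once = assign_crowns_to_seeds(cm, seeds_a)
        twice = assign_crowns_to_seeds(once, seeds_a)
        other = assign_crowns_to_seeds(cm, seeds_b)
        np.testing.assert_array_equal(once.labels, twice.labels)
        np.testing.assert_array_equal(once.labels, other.labels)

    def test_duplicate_seed_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SeedTable([1, 1], [0, 1], [0, 0])


class TestSeedGrid:
    def test_single_row(self):
        seeds = generate_seed_grid((0, 0), (1, 0), 1.75, 5.0, 1, 3)
        np.testing.assert_allclose(seeds.xy[:, 0], [0, 1.75, 3.5])
        np.testing.assert_allclose(seeds.xy[:, 1], 0)

    def test_two_rows(self):
        seeds = generate_seed_grid((10, 20), (1, 0), 7.0, 5.0, 2, 2)
        expected = {(10, 20), (17, 20), (10, 25), (17, 25)}
        assert {tuple(p) for p in seeds.xy} == expected

    def test_hedgerow_trial_geometry(self):
        seeds = generate_seed_grid((0, 0), (1, 0), 1.75, 5.0, 3, 20)
        assert len(seeds) == 60
        from scipy.spatial.distance import pdist

        assert pdist(seeds.xy).min() == pytest.approx(1.75)


class TestCountingAccuracy:
    @pytest.mark.parametrize(
        "detected, observed, expected",
        [(764, 806, 94.8), (228, 244, 93.4), (794, 804, 98.8), (243, 243, 100.0), (0, 10, 0.0)],
    )
    def test_reported_values(self, detected, observed, expected):
        assert counting_accuracy(detected, observed) == expected

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            counting_accuracy(5, 0)
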