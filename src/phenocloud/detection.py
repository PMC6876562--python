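"""Tree-point classification and individual crown delineation.

Points at least 0.3 m above the terrain are classified as tree points
(the threshold suits very young trees on fields without cover crops).
Their planimetric projection is rasterized onto a 0.1 m occupancy grid;
8-connected components of occupied cells form individual crowns, and
point-free background pockets fully enclosed by a crown are filled into
it (photogrammetric clouds rarely see the crown interior from above).

Components smaller than ``min_cells`` cells (default 3, i.e. 0.03 m^2)
are discarded as photogrammetric noise before labelling is finalized.

In a hedgerow planting the canopies of adjacent trees touch and merge
into one component; the known tree locations (seeds) split them: every
crown cell whose centre lies within 1 m of a seed is assigned to the
nearest seed (tie -> lower tree id), and remaining cells keep labels in
a namespace disjoint from the seed ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .pointcloud import PointCloud

__all__ = [
    "OccupancyGrid",
    "CrownMap",
    "SeedTable",
    "classify_tree_points",
    "rasterize_occupancy",
    "delineate_crowns",
    "assign_crowns_to_seeds",
    "generate_seed_grid",
    "counting_accuracy",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class OccupancyGrid:
    """Boolean presence raster of tree points, indexed ``[iy, ix]``."""

    origin: tuple[float, float]
    cell_size: float
    occupied: np.ndarray

    def cell_centers(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """(n, 2) centres of the cells selected by ``mask`` (default: all
        occupied)."""
        if mask is None:
            mask = self.occupied
        iy, ix = np.nonzero(mask)
        return np.column_stack(
            [
                self.origin[0] + (ix + 0.5) * self.cell_size,
                self.origin[1] + (iy + 0.5) * self.cell_size,
            ]
        )


@dataclass
class CrownMap:
    """Labelled crown raster.

    ``labels`` holds 0 for background and a positive tree id per crown
    cell; ``interior_mask`` marks the filled, point-free cells.  After
    seed assignment, ids of components (or component remnants) that fell
    outside every seed radius are listed in ``unassigned_ids``.
    """

    origin: tuple[float, float]
    cell_size: float
    labels: np.ndarray
    interior_mask: np.ndarray
    unassigned_ids: frozenset = field(default_factory=frozenset)

    @property
    def tree_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def cell_centers(self, tree_id: int) -> np.ndarray:
        mask = self.labels == tree_id
        if not mask.any():
            raise KeyError(f"tree id {tree_id} not present in crown map")
        iy, ix = np.nonzero(mask)
        return np.column_stack(
            [
                self.origin[0] + (ix + 0.5) * self.cell_size,
                self.origin[1] + (iy + 0.5) * self.cell_size,
            ]
        )


class SeedTable:
    """Known tree locations: rows of (tree_id, x, y) with unique ids."""

    def __init__(self, tree_ids, x, y):
        self.tree_ids = np.asarray(tree_ids, dtype=int).ravel()
        self.xy = np.column_stack(
            [np.asarray(x, dtype=float).ravel(), np.asarray(y, dtype=float).ravel()]
        )
        if self.tree_ids.shape[0] != self.xy.shape[0]:
            raise ValueError("tree_ids and coordinates must have equal length")
        if len(np.unique(self.tree_ids)) != len(self.tree_ids):
            raise ValueError("seed tree ids must be unique")

    def __len__(self) -> int:
        return len(self.tree_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"tree_id": self.tree_ids, "x": self.xy[:, 0], "y": self.xy[:, 1]})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SeedTable":
        df = pd.read_csv(path)
        return cls(df["tree_id"], df["x"], df["y"])


def classify_tree_points(pc: PointCloud, threshold: float = 0.3) -> PointCloud:
    """Retain points with height above terrain >= ``threshold`` (inclusive).

    Requires normalized heights; raises ``ValueError`` pointing at
    ``normalize_heights`` otherwise.
    """
    if pc.height_above_terrain is None:
        raise ValueError(
            "point cloud has no height_above_terrain; run "
            "phenocloud.dtm.normalize_heights first"
        )
    return pc.select(pc.height_above_terrain >= threshold)


def rasterize_occupancy(tree_pc: PointCloud, cell_size: float = 0.1,
                        origin: Optional[tuple[float, float]] = None) -> OccupancyGrid:
    """Mark every grid cell containing >= 1 tree point (half-open bins).

    The grid origin is floor-aligned to ``cell_size`` unless given, so the
    raster is reproducible regardless of point order.
    """
    if len(tree_pc) == 0:
        org = origin if origin is not None else (0.0, 0.0)
        return OccupancyGrid(org, cell_size, np.zeros((0, 0), dtype=bool))
    if origin is None:
        origin = (
            math.floor(tree_pc.x.min() / cell_size) * cell_size,
            math.floor(tree_pc.y.min() / cell_size) * cell_size,
        )
    ix = np.floor((tree_pc.x - origin[0]) / cell_size).astype(int)
    iy = np.floor((tree_pc.y - origin[1]) / cell_size).astype(int)
    if ix.min() < 0 or iy.min() < 0:
        raise ValueError("given origin does not cover the tree-point extent")
    occ = np.zeros((iy.max() + 1, ix.max() + 1), dtype=bool)
    occ[iy, ix] = True
    return OccupancyGrid(origin, cell_size, occ)


def _relabel_scan_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in order of first (row, col) appearance."""
    flat = labels.ravel()
    values, first = np.unique(flat, return_index=True)
    keep = values > 0
    values, first = values[keep], first[keep]
    if values.size == 0:
        return labels
    by_first = values[np.argsort(first)]
    mapping = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    mapping[by_first] = np.arange(1, by_first.size + 1)
    return mapping[labels]


def delineate_crowns(occ: OccupancyGrid, min_cells: int = 3) -> CrownMap:
    """Label 8-connected crowns and fill enclosed interior pockets.

    Components of fewer than ``min_cells`` cells are dropped as noise.
    Labels are assigned 1..K in raster-scan order of each component's
    first cell, so the output is reproducible.  Background regions not
    connected to the grid border are interior pockets: each is merged
    into its enclosing crown (majority of adjacent labels, tie -> lower)
    and recorded in ``interior_mask``.
    """
    if occ.occupied.size == 0:
        empty = np.zeros_like(occ.occupied, dtype=int)
        return CrownMap(occ.origin, occ.cell_size, empty, empty.astype(bool))
    labels, n = ndimage.label(occ.occupied, structure=_EIGHT)
    if n and min_cells > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_cells)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    labels = _relabel_scan_order(labels)
    interior = np.zeros_like(labels, dtype=bool)

    background = labels == 0
    bg_labels, n_bg = ndimage.label(background)  # 4-connectivity complements 8
    if n_bg:
        border = np.zeros_like(background, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        open_ids = set(np.unique(bg_labels[border & background]).tolist())
        for bg_id in range(1, n_bg + 1):
            if bg_id in open_ids:
                continue
            region = bg_labels == bg_id
            ring = ndimage.binary_dilation(region, structure=_EIGHT) & ~region
            neigh = labels[ring]
            neigh = neigh[neigh > 0]
            if neigh.size == 0:
                continue
            counts = np.bincount(neigh)
            enclosing = int(np.flatnonzero(counts == counts.max())[0])
            labels[region] = enclosing
            interior[region] = True
    return CrownMap(occ.origin, occ.cell_size, labels, interior)


def assign_crowns_to_seeds(crown_map: CrownMap, seeds: SeedTable,
                           radius: float = 1.0) -> CrownMap:
    """Split/relabel crown cells by known tree locations.

    Every labelled cell whose centre is within ``radius`` of at least one
    seed is relabelled to the nearest seed's tree id (tie -> lower id).
    Cells beyond every seed radius keep per-component labels renumbered
    into a namespace starting above the largest seed id and are flagged
    in ``unassigned_ids``.  Idempotent, and invariant to seed ordering.
    """
    if len(seeds) == 0:
        raise ValueError("seed table is empty")
    labels = crown_map.labels
    mask = labels > 0
    iy, ix = np.nonzero(mask)
    centers = np.column_stack(
        [
            crown_map.origin[0] + (ix + 0.5) * crown_map.cell_size,
            crown_map.origin[1] + (iy + 0.5) * crown_map.cell_size,
        ]
    )
    order = np.argsort(seeds.tree_ids, kind="stable")
    seed_ids = seeds.tree_ids[order]
    seed_xy = seeds.xy[order]
    tree = cKDTree(seed_xy)
    kq = min(8, len(seed_ids))
    dist, idx = tree.query(centers, k=kq)
    dist = dist.reshape(len(centers), kq)
    idx = idx.reshape(len(centers), kq)
    # nearest with tie -> lower tree id: among near-ties pick smallest id
    tied = dist <= dist[:, :1] + 1e-9
    cand_ids = np.where(tied, seed_ids[idx], np.iinfo(np.int64).max)
    nearest_id = cand_ids.min(axis=1)
    within = dist[:, 0] <= radius

    new_labels = np.zeros_like(labels)
    new_labels[iy[within], ix[within]] = nearest_id[within]

    unassigned: set[int] = set()
    if (~within).any():
        base = int(seed_ids.max())
        # stable renumbering keyed on the current label so reapplication
        # with the same seeds is a no-op
        old = labels[iy[~within], ix[~within]]
        remap = {}
        for o in np.unique(old):
            remap[o] = o if o > base else base + int(o)
        relabelled = np.array([remap[o] for o in old], dtype=labels.dtype)
        new_labels[iy[~within], ix[~within]] = relabelled
        unassigned = {int(v) for v in np.unique(relabelled)}
    return CrownMap(
        crown_map.origin,
        crown_map.cell_size,
        new_labels,
        crown_map.interior_mask.copy(),
        frozenset(unassigned),
    )


def generate_seed_grid(origin: tuple[float, float], row_direction: tuple[float, float],
                       tree_spacing: float, row_spacing: float,
                       n_rows: int, n_trees_per_row: int,
                       start_id: int = 1) -> SeedTable:
    """Regular planting grid of seed positions with sequential ids.

    Trees run along ``row_direction`` at ``tree_spacing``; rows are offset
    perpendicular to it (90 deg counter-clockwise) by ``row_spacing``.
    """
    if tree_spacing <= 0 or row_spacing <= 0:
        raise ValueError("spacings must be positive")
    d = np.asarray(row_direction, dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("row_direction must be non-zero")
    u = d / norm
    v = np.array([-u[1], u[0]])
    ids, xs, ys = [], [], []
    tid = start_id
    for r in range(n_rows):
        for t in range(n_trees_per_row):
            p = np.asarray(origin, dtype=float) + u * (t * tree_spacing) + v * (r * row_spacing)
            ids.append(tid)
            xs.append(p[0])
            ys.append(p[1])
            tid += 1
    return SeedTable(ids, xs, ys)


def counting_accuracy(detected: int, observed: int) -> float:
    """Detected / observed * 100, rounded to 1 decimal for reporting."""
    if observed <= 0:
        raise ValueError(f"observed count must be positive, got {observed}")
    if detected < 0:
        raise ValueError(f"detected count must be >= 0, got {detected}")
    return round(detected / observed * 100.0, 1)
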