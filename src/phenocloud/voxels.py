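"""Voxel slicing of the tree point cloud and crown volume.

The tree point cloud is cut into a regular 3D grid of 0.1 m voxels: the
planimetric grid matches the crown raster, and the vertical axis is the
normalized height, sliced bottom-to-top from the terrain (k = 0 is the
first decimetre above ground).  A voxel is occupied when at least one
point falls in it; multiple points in the same voxel count once, so the
representation is insensitive to oversampling.

From the voxel set a 2D "Voxels" layer is built: per grid cell, the
number of occupied voxels in that vertical column (gaps in the column do
not count).  Crown volume is then the sum of the column counts over a
tree's cells times the voxel volume (0.1 x 0.1 x 0.1 m^3).

Interior crown cells (point-free cells enclosed by the crown) have no
voxels of their own; they receive the rounded (half-up) mean of the
counts of their point-bearing 8-neighbour crown cells -- a conservative,
configurable stand-in for the unobserved crown core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import CrownMap
from .pointcloud import PointCloud

__all__ = ["VoxelSet", "VoxelColumnLayer", "voxelize", "column_counts", "crown_volume"]


@dataclass
class VoxelSet:
    """Occupied voxel indices (ix, iy, k), anchored at the crown-grid
    origin planimetrically and at terrain level (k = 0) vertically."""

    origin: tuple[float, float]
    voxel_size: float
    indices: np.ndarray  # (m, 3) int, unique rows

    def __len__(self) -> int:
        return self.indices.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.indices, columns=["i", "j", "k"]).to_csv(path, index=False)


@dataclass
class VoxelColumnLayer:
    """Per-cell count of occupied voxels in the column ("Voxels" layer).

    Carries the crown labels it was built against so per-tree sums need
    no extra argument.
    """

    origin: tuple[float, float]
    cell_size: float
    counts: np.ndarray  # (ny, nx) int
    labels: np.ndarray  # crown labels, same shape

    def to_ascii_grid(self, path) -> None:
        from .dtm import write_ascii_grid

        write_ascii_grid(path, self.counts.astype(float), self.origin, self.cell_size)

    def to_csv(self, path) -> None:
        import pandas as pd

        iy, ix = np.nonzero(self.counts)
        pd.DataFrame(
            {"i": ix, "j": iy, "count": self.counts[iy, ix], "tree_id": self.labels[iy, ix]}
        ).to_csv(path, index=False)


def voxelize(tree_pc: PointCloud, voxel_size: float = 0.1,
             origin: tuple[float, float] | None = None) -> VoxelSet:
    """Bin tree points into voxels; half-open bins on all three axes.

    Requires normalized heights.  Points with negative height above
    terrain are excluded (no voxels below ground level).
    """
    if tree_pc.height_above_terrain is None:
        raise ValueError("voxelize requires normalized heights; run normalize_heights")
    if origin is None:
        if len(tree_pc) == 0:
            return VoxelSet((0.0, 0.0), voxel_size, np.zeros((0, 3), dtype=int))
        origin = (
            np.floor(tree_pc.x.min() / voxel_size) * voxel_size,
            np.floor(tree_pc.y.min() / voxel_size) * voxel_size,
        )
    hat = tree_pc.height_above_terrain
    keep = hat >= 0
    ix = np.floor((tree_pc.x[keep] - origin[0]) / voxel_size).astype(int)
    iy = np.floor((tree_pc.y[keep] - origin[1]) / voxel_size).astype(int)
    k = np.floor(hat[keep] / voxel_size).astype(int)
    idx = np.unique(np.column_stack([ix, iy, k]), axis=0)
    return VoxelSet((float(origin[0]), float(origin[1])), voxel_size, idx)


def column_counts(vox: VoxelSet, crown_map: CrownMap) -> VoxelColumnLayer:
    """Count occupied voxels per column, restricted to crown cells.

    Point-bearing crown cells get their true column count; interior
    (filled) crown cells get the rounded half-up mean of the counts of
    their point-bearing 8-neighbour crown cells (0 when none); all other
    cells are 0.  Requires the voxel set and the crown map to share
    origin and planimetric cell size.
    """
    if abs(vox.voxel_size - crown_map.cell_size) > 1e-12 or (
        abs(vox.origin[0] - crown_map.origin[0]) > 1e-9
        or abs(vox.origin[1] - crown_map.origin[1]) > 1e-9
    ):
        raise ValueError(
            "voxel set and crown map geometries differ "
            f"(origins {vox.origin} vs {crown_map.origin}, sizes "
            f"{vox.voxel_size} vs {crown_map.cell_size})"
        )
    labels = crown_map.labels
    ny, nx = labels.shape
    counts = np.zeros((ny, nx), dtype=int)
    if len(vox):
        ix, iy = vox.indices[:, 0], vox.indices[:, 1]
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(counts, (iy[inside], ix[inside]), 1)
    crown = labels > 0
    counts[~crown] = 0
    interior = crown_map.interior_mask & crown
    # interior cells carry no points by construction; estimate from the
    # point-bearing neighbours of each
    bearing = crown & ~interior & (counts > 0)
    if interior.any():
        iy, ix = np.nonzero(interior)
        est = np.zeros(len(iy), dtype=int)
        for n, (r, c) in enumerate(zip(iy, ix)):
            r0, r1 = max(r - 1, 0), min(r + 2, ny)
            c0, c1 = max(c - 1, 0), min(c + 2, nx)
            window = bearing[r0:r1, c0:c1]
            vals = counts[r0:r1, c0:c1][window]
            if vals.size:
                est[n] = int(np.floor(vals.mean() + 0.5))  # round half-up
        counts[iy, ix] = est
    return VoxelColumnLayer(crown_map.origin, crown_map.cell_size, counts, labels.copy())


def crown_volume(layer: VoxelColumnLayer, tree_id: int) -> float:
    """Crown volume in m^3: sum of column counts over the tree's cells
    times the voxel volume."""
    mask = layer.labels == tree_id
    if not mask.any():
        raise KeyError(f"tree id {tree_id} not present in the layer")
    return float(layer.counts[mask].sum()) * layer.cell_size ** 3
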