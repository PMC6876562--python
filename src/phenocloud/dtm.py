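"""Digital terrain model from chessboard tiles and the lowest-points rule.

The terrain under a young orchard is recovered directly from the point
cloud: the cloud is partitioned into square tiles (chessboard
segmentation, default 2 m side, sized to the tree dimensions and planting
pattern), and each tile's ground elevation is the mean of its 15 % lowest
points.  The fraction works because even a tile containing a young tree
is mostly ground hits; the lowest points sample the terrain, not the
canopy.  The resulting DTM is piecewise-constant per tile.

Rounding rule: the number of lowest points averaged is k = ceil(fraction
* n), minimum 1, so tiny tiles still yield a value.  Tiles with no points
are filled from the nearest non-empty tile centre (ties broken toward the
lowest elevation) and flagged in ``fill_mask``.

Normalized height (height above terrain) of a point is its z minus the
elevation of the tile containing it.  Slightly negative values occur for
ground noise below the local tile estimate and are retained; they are
only clipped later, at tree-point classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import PointCloud
from .validation import RegressionStats, regression_stats

__all__ = [
    "DTMGrid",
    "tile_ground_elevation",
    "build_dtm",
    "normalize_heights",
    "compare_dtm",
]


@dataclass
class DTMGrid:
    """Per-tile terrain elevations.

    ``elevations`` is indexed ``[iy, ix]``; the tile with index (ix, iy)
    covers ``[origin_x + ix*t, origin_x + (ix+1)*t) x [origin_y + iy*t,
    origin_y + (iy+1)*t)`` with t = ``tile_size``.  ``fill_mask`` flags
    tiles whose value was interpolated from neighbours rather than
    estimated from points.
    """

    origin: tuple[float, float]
    tile_size: float
    elevations: np.ndarray
    fill_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    def tile_index(self, x, y):
        """(ix, iy) arrays of the tiles containing the given coordinates."""
        ix = np.floor((np.asarray(x, dtype=float) - self.origin[0]) / self.tile_size).astype(int)
        iy = np.floor((np.asarray(y, dtype=float) - self.origin[1]) / self.tile_size).astype(int)
        return ix, iy

    def elevation_at(self, x, y) -> np.ndarray:
        """Terrain elevation under each (x, y); error outside the grid."""
        ix, iy = self.tile_index(x, y)
        ny, nx = self.elevations.shape
        bad = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            xx = np.atleast_1d(np.asarray(x, dtype=float))[i]
            yy = np.atleast_1d(np.asarray(y, dtype=float))[i]
            raise ValueError(f"point ({xx}, {yy}) lies outside the DTM extent")
        return self.elevations[iy, ix]

    def tile_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.elevations.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.tile_size
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.tile_size
        return cx, cy

    def to_csv(self, path) -> None:
        """Export tiles as CSV: i, j, x_center, y_center, elevation, filled."""
        import pandas as pd

        ny, nx = self.elevations.shape
        iy, ix = np.mgrid[0:ny, 0:nx]
        cx, cy = self.tile_centers()
        pd.DataFrame(
            {
                "i": ix.ravel(),
                "j": iy.ravel(),
                "x_center": cx[ix.ravel()],
                "y_center": cy[iy.ravel()],
                "elevation": self.elevations.ravel(),
                "filled": self.fill_mask.ravel().astype(int),
            }
        ).to_csv(path, index=False)

    def to_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        """Export as an ESRI ASCII grid (plain-text raster)."""
        write_ascii_grid(path, self.elevations, self.origin, self.tile_size, nodata)


def write_ascii_grid(path, array: np.ndarray, origin: tuple[float, float],
                     cell_size: float, nodata: float = -9999.0) -> None:
    """ESRI ASCII raster: header then rows from the top (max y) down."""
    ny, nx = array.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size}\nNODATA_value {nodata}\n"
    )
    data = np.where(np.isfinite(array), array, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        for row in data[::-1]:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def tile_ground_elevation(z_values: Sequence[float], fraction: float = 0.15) -> float:
    """Mean of the k lowest elevations, k = ceil(fraction * n), k >= 1.

    Raises ``ValueError`` for an empty tile (the caller interpolates
    those) or a fraction outside (0, 1].
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    z = np.asarray(z_values, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty tile: no points to estimate ground elevation")
    k = max(1, math.ceil(fraction * z.size))
    return float(np.partition(z, k - 1)[:k].mean())


def build_dtm(pc: PointCloud, tile_size: float = 2.0, fraction: float = 0.15) -> DTMGrid:
    """Chessboard-segment the cloud and estimate per-tile ground elevation.

    The grid is anchored at ``(floor(xmin/t)*t, floor(ymin/t)*t)`` so the
    result does not depend on point order.  Empty tiles are filled by the
    nearest non-empty tile centre (ties -> lowest elevation) and flagged.
    """
    if len(pc) == 0:
        raise ValueError("cannot build a DTM from an empty point cloud")
    ox = math.floor(pc.x.min() / tile_size) * tile_size
    oy = math.floor(pc.y.min() / tile_size) * tile_size
    nx = int(np.floor((pc.x.max() - ox) / tile_size)) + 1
    ny = int(np.floor((pc.y.max() - oy) / tile_size)) + 1

    ix = np.floor((pc.x - ox) / tile_size).astype(int)
    iy = np.floor((pc.y - oy) / tile_size).astype(int)
    flat = iy * nx + ix

    # Sort points by (tile, z); per-tile k-lowest means via prefix sums.
    order = np.lexsort((pc.z, flat))
    flat_sorted = flat[order]
    z_sorted = pc.z[order]
    tiles, starts, counts = np.unique(flat_sorted, return_index=True, return_counts=True)
    k = np.maximum(1, np.ceil(fraction * counts).astype(int))
    csum = np.concatenate([[0.0], np.cumsum(z_sorted)])
    sums = csum[starts + k] - csum[starts]

    elevations = np.full((ny, nx), np.nan)
    elevations.ravel()[tiles] = sums / k
    fill_mask = ~np.isfinite(elevations)

    if fill_mask.any():
        cx, cy = np.meshgrid(
            ox + (np.arange(nx) + 0.5) * tile_size,
            oy + (np.arange(ny) + 0.5) * tile_size,
        )
        good = ~fill_mask
        tree = cKDTree(np.column_stack([cx[good], cy[good]]))
        good_elev = elevations[good]
        empty_xy = np.column_stack([cx[fill_mask], cy[fill_mask]])
        kq = min(8, len(good_elev))
        dist, idx = tree.query(empty_xy, k=kq)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        # among neighbours tied for nearest (within 1e-9), take the lowest
        tied = dist <= dist[:, :1] + 1e-9
        cand = np.where(tied, good_elev[idx], np.inf)
        elevations[fill_mask] = cand.min(axis=1)
    return DTMGrid((ox, oy), tile_size, elevations, fill_mask)


def normalize_heights(pc: PointCloud, dtm: DTMGrid) -> PointCloud:
    """Attach height above terrain: z minus the containing tile's elevation.

    Negative values (noise below the terrain estimate) are kept.  Points
    outside the DTM extent raise ``ValueError`` naming the point.
    """
    ground = dtm.elevation_at(pc.x, pc.y)
    return pc.with_heights(pc.z - ground)


def compare_dtm(dtm: DTMGrid, reference_samples, grid_spacing: Optional[float] = 20.0,
                exclude_mask=None) -> RegressionStats:
    """Regress DTM elevations against reference elevations at sample points.

    ``reference_samples`` is an (n, 3) array-like of (x, y, elevation).
    When ``grid_spacing`` is set, at most one sample per grid cell of that
    spacing is kept (emulating validation on a coarse regular grid).
    ``exclude_mask`` flags anomalous samples to dismiss.  RMSE here is
    measured about the fitted line (the comparison is between two terrain
    models that may carry a datum offset); R^2 is offset-invariant either
    way.
    """
    samples = np.asarray(reference_samples, dtype=float).reshape(-1, 3)
    if exclude_mask is not None:
        samples = samples[~np.asarray(exclude_mask, dtype=bool)]
    if grid_spacing:
        cell = np.floor(samples[:, :2] / grid_spacing).astype(int)
        _, keep = np.unique(cell, axis=0, return_index=True)
        samples = samples[np.sort(keep)]
    if samples.shape[0] < 3:
        raise ValueError(f"need >= 3 usable samples, got {samples.shape[0]}")
    estimated = dtm.elevation_at(samples[:, 0], samples[:, 1])
    return regression_stats(samples[:, 2], estimated, rmse_about="fit")
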