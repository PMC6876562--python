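"""Minimal unit-checked point-cloud data model.

A :class:`PointCloud` is the sole input of the pipeline: an (n, 3) array of
x, y, z coordinates in a projected (metric) reference frame, where z is the
elevation above sea level.  After terrain normalization a per-point
``height_above_terrain`` attribute (metres above the local DTM tile) is
attached; it is absent until then.

All spatial binning in this package uses half-open intervals ``[min, max)``
so a point on a shared cell border is counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["PointCloud", "BoundingBox", "point_density", "crop"]

# EPSG codes in the 4000-4999 block are geographic (lat/lon) coordinate
# reference systems; a handful of common ones are listed explicitly so the
# error message can be precise even if the heuristic changes.
_KNOWN_GEOGRAPHIC_EPSG = {4326, 4258, 4269, 4267, 4230, 4979}


def _is_geographic_crs(crs: str) -> bool:
    code = _epsg_code(crs)
    if code is None:
        return False
    return code in _KNOWN_GEOGRAPHIC_EPSG or 4000 <= code <= 4999


def _epsg_code(crs: str) -> Optional[int]:
    text = crs.strip().upper()
    if text.startswith("EPSG:"):
        try:
            return int(text.split(":", 1)[1])
        except ValueError:
            return None
    return None


@dataclass
class BoundingBox:
    """Axis-aligned planimetric extent in metres, half-open on use."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate bounding box: ({self.xmin}, {self.ymin}) .. "
                f"({self.xmax}, {self.ymax})"
            )

    @property
    def area(self) -> float:
        """Planimetric area in m^2."""
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)


@dataclass
class PointCloud:
    """3D point cloud with optional normalized heights.

    Parameters
    ----------
    xyz
        ``(n, 3)`` float array of x, y, z coordinates in metres.  z is the
        altitude above sea level as produced by photogrammetric
        reconstruction.
    crs
        Optional coordinate-reference-system identifier (``"EPSG:<code>"``).
        Must be a projected, metric system; geographic lat/lon CRSs are
        rejected because every threshold in the pipeline is in metres.
    height_above_terrain
        Optional per-point height above the terrain model, metres.  Set by
        :func:`phenocloud.dtm.normalize_heights`; may contain small negative
        values (photogrammetric noise below the terrain), which are kept.
    """

    xyz: np.ndarray
    crs: Optional[str] = None
    height_above_terrain: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=np.float64))
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must have shape (n, 3), got {self.xyz.shape}")
        if not np.isfinite(self.xyz).all():
            raise ValueError("point coordinates must all be finite")
        if self.crs is not None and _is_geographic_crs(self.crs):
            raise ValueError(
                f"geographic CRS {self.crs!r} is not supported: coordinates "
                "must be in a projected, metric system"
            )
        if self.height_above_terrain is not None:
            hat = np.asarray(self.height_above_terrain, dtype=np.float64).ravel()
            if hat.shape[0] != len(self):
                raise ValueError(
                    f"height_above_terrain has {hat.shape[0]} values for "
                    f"{len(self)} points"
                )
            self.height_above_terrain = hat

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def bounding_box(self) -> BoundingBox:
        """Tight planimetric bounds; for binning purposes the max edge is
        treated as exclusive, so callers typically pad it by an epsilon."""
        if len(self) == 0:
            raise ValueError("empty point cloud has no bounding box")
        pad = 1e-9  # keep xmin < xmax for single points / degenerate extents
        return BoundingBox(
            float(self.x.min()),
            float(self.y.min()),
            float(self.x.max()) + pad,
            float(self.y.max()) + pad,
        )

    def with_heights(self, heights: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz.copy(), crs=self.crs, height_above_terrain=heights)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or index array, carrying heights along."""
        hat = None
        if self.height_above_terrain is not None:
            hat = self.height_above_terrain[mask]
        return PointCloud(self.xyz[mask], crs=self.crs, height_above_terrain=hat)


def point_density(pc: PointCloud, area) -> float:
    """Points per square metre over ``area`` (a number in m^2 or a
    :class:`BoundingBox`).

    Raises ``ValueError`` for a non-positive area.
    """
    if isinstance(area, BoundingBox):
        area = area.area
    area = float(area)
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    return len(pc) / area


def crop(pc: PointCloud, box: BoundingBox) -> PointCloud:
    """Points with ``xmin <= x < xmax`` and ``ymin <= y < ymax``.

    Half-open on the max edges, like every spatial bin in the package.  An
    empty result is allowed.
    """
    mask = (
        (pc.x >= box.xmin)
        & (pc.x < box.xmax)
        & (pc.y >= box.ymin)
        & (pc.y < box.ymax)
    )
    return pc.select(mask)
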