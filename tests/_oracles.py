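"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations kept separate from the package code
paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_crop(xyz: np.ndarray, xmin, ymin, xmax, ymax) -> np.ndarray:
    keep = []
    for p in xyz:
        if xmin <= p[0] < xmax and ymin <= p[1] < ymax:
            keep.append(p)
    return np.array(keep).reshape(-1, 3)


def brute_force_bins(xy: np.ndarray, origin, cell_size) -> set:
    """Per-point half-open binning, one cell index pair per point."""
    cells = set()
    for x, y in xy:
        cells.add((int(np.floor((x - origin[0]) / cell_size)),
                   int(np.floor((y - origin[1]) / cell_size))))
    return cells


def brute_force_voxels(xyz_h: np.ndarray, origin, size) -> set:
    """(ix, iy, k) occupied voxel set; rows are (x, y, height)."""
    vox = set()
    for x, y, h in xyz_h:
        if h < 0:
            continue
        vox.add((int(np.floor((x - origin[0]) / size)),
                 int(np.floor((y - origin[1]) / size)),
                 int(np.floor(h / size))))
    return vox


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def count_components_union_find(occupied: np.ndarray) -> int:
    """Number of 8-connected components of True cells, by union-find over
    every adjacent occupied pair."""
    ny, nx = occupied.shape
    uf = UnionFind(ny * nx)
    flat_ids = np.arange(ny * nx).reshape(ny, nx)
    for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
        a_rows = slice(max(0, -dr), ny - max(0, dr))
        a_cols = slice(max(0, -dc), nx - max(0, dc))
        b_rows = slice(max(0, dr), ny - max(0, -dr))
        b_cols = slice(max(0, dc), nx - max(0, -dc))
        both = occupied[a_rows, a_cols] & occupied[b_rows, b_cols]
        for a, b in zip(flat_ids[a_rows, a_cols][both], flat_ids[b_rows, b_cols][both]):
            uf.union(int(a), int(b))
    occupied_ids = flat_ids[occupied]
    return len({uf.find(int(i)) for i in occupied_ids})


def nearest_seed_assignment(centers: np.ndarray, seed_ids: np.ndarray,
                            seed_xy: np.ndarray, radius: float) -> np.ndarray:
    """Per cell-centre nearest seed id within radius (tie -> lower id),
    or 0 when no seed is within radius."""
    out = np.zeros(len(centers), dtype=int)
    for n, c in enumerate(centers):
        best_d, best_id = np.inf, 0
        for sid, s in zip(seed_ids, seed_xy):
            d = float(np.hypot(*(c - s)))
            if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and sid < best_id):
                best_d, best_id = d, int(sid)
        if best_d <= radius:
            out[n] = best_id
    return out


def corner_diameter(cell_centers: np.ndarray, cell_size: float) -> float:
    """Rotating-calipers-style diameter over the cell squares: the max
    distance between any two corners of any two cells (brute force)."""
    half = cell_size / 2.0
    corners = []
    for cx, cy in cell_centers:
        for dx in (-half, half):
            for dy in (-half, half):
                corners.append((cx + dx, cy + dy))
    corners = np.array(corners)
    diff = corners[:, None, :] - corners[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2).max()))
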