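"""End-to-end pipeline: LAS in, DTM + crowns + voxels + trait table out.

The run is fully automatic: terrain model, height normalization,
tree-point classification, crown delineation (with optional seed-based
splitting for hedgerows), voxel column counts and per-tree traits.  All
stage outputs plus a manifest (config echo, versions, counts, timings)
are written to the output directory; identical inputs and configuration
reproduce identical trait tables.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .detection import (
    SeedTable,
    assign_crowns_to_seeds,
    classify_tree_points,
    delineate_crowns,
    generate_seed_grid,
    rasterize_occupancy,
)
from .dtm import build_dtm, normalize_heights
from .las import read_point_cloud
from .traits import characterize_trees, export_records, records_to_dataframe
from .voxels import column_counts, voxelize

logger = logging.getLogger("phenocloud")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline, with the field defaults.

    ``voxel_size`` must equal ``cell_size``: one 0.1 m resolution is used
    for both the crown raster and the voxel grid.
    """

    input_path: str = ""
    output_dir: str = "phenocloud_out"
    tile_size: float = 2.0
    ground_fraction: float = 0.15
    tree_threshold: float = 0.3
    cell_size: float = 0.1
    voxel_size: float = 0.1
    seed_radius: float = 1.0
    min_crown_cells: int = 3
    mode: str = "single_tree"  # single_tree | hedgerow
    seeds_csv: Optional[str] = None
    # planting-pattern fallback for hedgerow mode when no seed CSV exists
    planting: Optional[dict] = None  # origin, row_direction, tree_spacing, row_spacing, n_rows, n_trees_per_row
    export_dialect: str = "geojson"

    def __post_init__(self) -> None:
        for name in ("tile_size", "tree_threshold", "cell_size", "voxel_size", "seed_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.voxel_size - self.cell_size) > 1e-12:
            raise ValueError("voxel_size must equal cell_size (one shared 0.1 m resolution)")
        if not 0 < self.ground_fraction <= 1:
            raise ValueError("ground_fraction must be in (0, 1]")
        if self.mode not in ("single_tree", "hedgerow"):
            raise ValueError(f"mode must be single_tree or hedgerow, got {self.mode!r}")


@dataclass
class PipelineResult:
    dtm: object
    crown_map: object
    layer: object
    records: list
    outputs: dict = field(default_factory=dict)


def _resolve_seeds(config: PipelineConfig) -> Optional[SeedTable]:
    if config.seeds_csv:
        return SeedTable.from_csv(config.seeds_csv)
    if config.planting:
        p = config.planting
        return generate_seed_grid(
            tuple(p["origin"]), tuple(p.get("row_direction", (1.0, 0.0))),
            float(p["tree_spacing"]), float(p["row_spacing"]),
            int(p["n_rows"]), int(p["n_trees_per_row"]),
        )
    return None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages and write the artifact bundle.

    Outputs in ``config.output_dir``: ``dtm.asc``/``dtm.csv``,
    ``crowns.geojson``, ``voxels.asc``/``voxels.csv``, ``traits.csv`` and
    ``manifest.json``.  On a stage failure the partially written bundle
    is removed and the error names the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    stage = "setup"

    def _write(path: Path, fn) -> None:
        fn(path)
        written.append(path)

    try:
        stage = "read"
        t0 = time.perf_counter()
        pc = read_point_cloud(config.input_path)
        logger.info("read %d points from %s", len(pc), config.input_path)
        timings[stage] = time.perf_counter() - t0

        stage = "dtm"
        t0 = time.perf_counter()
        dtm = build_dtm(pc, config.tile_size, config.ground_fraction)
        normalized = normalize_heights(pc, dtm)
        _write(out / "dtm.asc", dtm.to_ascii_grid)
        _write(out / "dtm.csv", dtm.to_csv)
        logger.info("DTM %s tiles (%d interpolated)", dtm.shape, int(dtm.fill_mask.sum()))
        timings[stage] = time.perf_counter() - t0

        stage = "detect"
        t0 = time.perf_counter()
        tree_pc = classify_tree_points(normalized, config.tree_threshold)
        occ = rasterize_occupancy(tree_pc, config.cell_size)
        crown_map = delineate_crowns(occ, config.min_crown_cells)
        seeds = _resolve_seeds(config)
        if config.mode == "hedgerow":
            if seeds is None:
                raise ValueError(
                    "hedgerow mode needs tree seed locations: provide "
                    "seeds_csv or a planting pattern"
                )
            crown_map = assign_crowns_to_seeds(crown_map, seeds, config.seed_radius)
        logger.info(
            "classified %d tree points into %d crowns", len(tree_pc), len(crown_map.tree_ids)
        )
        timings[stage] = time.perf_counter() - t0

        stage = "voxels"
        t0 = time.perf_counter()
        vox = voxelize(tree_pc, config.voxel_size, origin=crown_map.origin)
        layer = column_counts(vox, crown_map)
        _write(out / "voxels.asc", layer.to_ascii_grid)
        _write(out / "voxels.csv", layer.to_csv)
        timings[stage] = time.perf_counter() - t0

        stage = "characterize"
        t0 = time.perf_counter()
        records = characterize_trees(crown_map, layer, tree_pc)
        export_records(
            records, out / "crowns.geojson", out / "traits.csv",
            crown_map=crown_map, dialect=config.export_dialect,
        )
        written += [out / "crowns.geojson", out / "traits.csv"]
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "versions": {
                "phenocloud": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
            },
            "counts": {
                "points": len(pc),
                "tree_points": len(tree_pc),
                "trees": len(records),
                "dtm_tiles": int(np.prod(dtm.shape)),
            },
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(out / "manifest.json")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = {p.name: str(p) for p in written}
    return PipelineResult(dtm, crown_map, layer, records, outputs)
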