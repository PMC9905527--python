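"""End-to-end orchestration: configuration -> summary-table tree + report.

A run is described by one declarative JSON file mirroring
:class:`RunConfig`; the pipeline samples each input in its native CRS,
finalizes the requested statistics, writes convention-named tables under
the standard directory layout, and collects every flagged geometry and
verification event in a log.  The process exits nonzero (raises) if any
verification fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rasters, tables, vectors
from .grid import GridSpec, ISEA3HGrid, cell_count
from .rasters import CRS, read_ascii_grid

logger = logging.getLogger("hexeco")

VALID_STATS = ("centroid", "fraction", "mode", "mean")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""
    resolution: int
    dataset: str
    version: str
    theme: str
    out_root: str
    inputs: list = field(default_factory=list)    # raster .asc / vector .geojson
    statistics: tuple = ("mean",)
    kind: str = "continuous"                      # or "discrete" / "vector"
    legend: list | None = None
    class_field: str = "class"
    years: tuple = ()
    null_codes: dict = field(default_factory=dict)
    mode_threshold: float = 0.2
    verify: bool = True
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        if not self.inputs:
            raise ValueError("config lists no inputs")
        bad = set(self.statistics) - set(VALID_STATS)
        if bad:
            raise ValueError(f"unknown statistics: {sorted(bad)}")
        if not 0 <= self.resolution <= self.grid.max_resolution:
            raise ValueError("resolution out of supported range")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        grid = GridSpec(**raw.pop("grid", {}))
        raw["statistics"] = tuple(raw.get("statistics", ("mean",)))
        raw["years"] = tuple(raw.get("years", ()))
        return cls(grid=grid, **raw)


_DEFAULT_NULLS = {"centroid": -100.0, "fraction": None,
                  "mode": -1, "mean": -1000.0}


def run_pipeline(cfg: RunConfig):
    """Execute one run; returns (paths written, verification report or None)."""
    grid = ISEA3HGrid(cfg.grid)
    for p in cfg.inputs:
        if not Path(p).exists():
            raise FileNotFoundError(f"input does not exist: {p}")
    written = []
    report = None
    nulls = {**_DEFAULT_NULLS, **cfg.null_codes}

    if cfg.kind == "vector":
        frames, report = _run_vector(cfg, grid)
    else:
        frames = _run_raster(cfg, grid, nulls)

    for stat, frame in frames.items():
        naming = tables.NamingConvention(cfg.dataset, cfg.version, cfg.theme,
                                         stat.capitalize(), cfg.years)
        path = tables.table_path(cfg.out_root, cfg.resolution, naming)
        table = tables.SummaryTable(frame, cfg.resolution, naming)
        tables.write_table(table, path)
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(frame))

    if report is not None and not report.passed:
        for item in report.containment_failures:
            logger.error("containment failure: %s", item)
        for lbl, (src, tot, err) in report.conservation.items():
            if abs(err) > report.conservation_tol:
                logger.error("conservation failure %s: %.6g vs %.6g", lbl,
                             tot, src)
        raise RuntimeError("verification failed; see log")
    return written, report


def _legend_columns(legend, stat):
    return [tables.column_name(str(c), stat.capitalize()) for c in legend]


def _run_raster(cfg: RunConfig, grid: ISEA3HGrid, nulls):
    ctab = rasters.ContingencyTable()
    sums = rasters.WeightedSums.empty()
    tiles = []
    pixel_area_hint = None
    for path in cfg.inputs:
        tile = read_ascii_grid(path)
        tiles.append(tile)
        hids = rasters.build_hid_tile(tile, cfg.resolution, grid)
        authalic = tile.authalic or tile.crs.is_equal_area
        areas = None if authalic else rasters.build_area_tile(tile)
        if authalic:
            t = tile.transform
            pixel_area_hint = abs(t.a * t.e - t.b * t.d) * 1e-6
        if cfg.kind == "discrete":
            ctab = ctab + rasters.crosstab_discrete(tile, hids, areas)
        else:
            sums = sums + rasters.accumulate_weighted(tile, hids, areas)

    frames = {}
    want = set(cfg.statistics)
    hid_all = np.arange(1, cell_count(cfg.resolution, cfg.grid) + 1)
    if "centroid" in want:
        col = pd.concat([rasters.stat_centroid(t, hid_all, cfg.resolution,
                                               grid, nulls["centroid"])
                         for t in tiles], axis=1).bfill(axis=1).iloc[:, 0]
        name = tables.column_name(cfg.theme, "Centroid")
        frames["centroid"] = col.to_frame(name)
    if cfg.kind == "discrete" and ({"fraction", "mode"} & want):
        if cfg.legend is None:
            raise ValueError("discrete sampling requires a legend")
        unknown = set(ctab.weights.index.get_level_values("klass")) \
            - set(cfg.legend)
        if unknown:
            raise ValueError(f"classes absent from legend: {sorted(unknown)}")
        if pixel_area_hint is not None:
            ctab = rasters.counts_to_area_weights(ctab, pixel_area_hint)
        frac = rasters.stat_fraction(ctab, cfg.resolution, cfg.legend,
                                     cfg.grid)
        if "fraction" in want:
            out = frac.copy()
            out.columns = _legend_columns(cfg.legend, "fraction")
            frames["fraction"] = out
        if "mode" in want:
            mode = rasters.stat_mode(frac, cfg.mode_threshold, nulls["mode"])
            frames["mode"] = mode.to_frame(tables.column_name(cfg.theme,
                                                              "Mode"))
    if cfg.kind == "continuous" and "mean" in want:
        mean = rasters.stat_mean(sums, nulls["mean"])
        frames["mean"] = mean.to_frame(tables.column_name(cfg.theme, "Mean"))
    return frames


def _run_vector(cfg: RunConfig, grid: ISEA3HGrid):
    polys = None
    for path in cfg.inputs:
        pset = vectors.read_geojson(path, cfg.class_field)
        polys = pset if polys is None else vectors.ClassedPolygonSet(
            polys.polygons + pset.polygons, polys.crs)
    polys = vectors.validate_simple_features(polys)
    for flag in polys.flags:
        logger.warning("geometry flag: %s", flag)
    polys = vectors.dissolve(polys, by_class=True)

    # limit cell generation to the classes' bounding latitudes/longitudes
    candidates = _candidate_hids(polys, cfg.resolution, grid)
    cells = vectors.cell_polygons(cfg.resolution, polys.crs, hids=candidates,
                                  grid=grid)
    records = vectors.intersect(cells, polys)
    report = vectors.verify(records, cells, polys) if cfg.verify else None
    legend = cfg.legend or polys.classes()
    frac = vectors.records_to_fractions(records, legend)
    frac.columns = _legend_columns(legend, "fraction")
    frac.index.name = "HID"
    return {"fraction": frac}, report


def _candidate_hids(polys, resolution, grid):
    from shapely.ops import unary_union
    hull = unary_union([g for _, g in polys.polygons]).envelope.buffer(
        2.0 * grid.centroid_spacing_km(resolution) / 111.0)
    N = cell_count(resolution, grid.spec)
    hid_all = np.arange(1, N + 1)
    lat, lon = grid.centroid(hid_all, resolution)
    lo_x, lo_y, hi_x, hi_y = hull.bounds
    m = (lat >= lo_y) & (lat <= hi_y) & (lon >= lo_x) & (lon <= hi_x)
    return hid_all[m]
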