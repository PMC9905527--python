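"""Vector polygon sampling workflow.

Class-attributed polygon datasets (species ranges, ecoregions, land
masks) are dissolved per class, validated against the OGC simple-feature
rules, and intersected with cell polygons generated in the dataset's
native CRS.  Per-(cell, class) geodesic areas, expressed as fractions of
the geodesic cell area, are the output.  Three integrity checks mirror
the production workflow: piece-in-cell containment (with a minimum
vertex count), per-class area conservation across all cells, and
fraction <= 1 per cell.

Straight polygon edges are straight in the source CRS plane and are
never re-densified geodesically: the dataset is taken as its authors
drew it in the system it is distributed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import (GeometryCollection, MultiPolygon, Polygon,
                              box, mapping, shape)
from shapely.ops import unary_union
from shapely.strtree import STRtree

from . import geodesy
from .grid import ISEA3HGrid, cell_count
from .rasters import CRS, Affine, RasterTile, build_hid_tile

__all__ = [
    "ClassedPolygonSet", "IntersectionRecord", "VerificationReport",
    "dissolve", "validate_simple_features", "cell_polygons",
    "intersect", "verify", "cross_resolution_index",
    "geodesic_geom_area_km2", "read_geojson", "write_geojson",
]


# ----------------------------------------------------------------------
def geodesic_geom_area_km2(geom, crs: CRS = None,
                           ell: geodesy.EllipsoidSpec = geodesy.WGS84) -> float:
    """Geodesic area of a shapely (multi)polygon given in ``crs``.

    Ring vertices are converted to lon/lat; edges are straight in the
    source CRS plane, which for geographic data coincides with the
    plate-carree edge rule of :func:`hexeco.geodesy.geodesic_polygon_area_km2`.
    Projected rings are densified in the source plane first so their
    curvature on the ellipsoid is represented.
    """
    crs = crs or CRS.geographic()

    def ring_area(ring_xy):
        xy = np.asarray(ring_xy, dtype=float)
        if not crs.is_geographic:
            xy = _densify_xy(xy, 20)
        lon, lat = crs.to_lonlat(xy[:, 0], xy[:, 1])
        return geodesy.geodesic_polygon_area_km2(
            np.stack([lat, lon], axis=1), ell)

    total = 0.0
    geoms = getattr(geom, "geoms", [geom])
    for g in geoms:
        if g.is_empty or not isinstance(g, Polygon):
            continue
        total += ring_area(g.exterior.coords)
        for hole in g.interiors:
            total -= ring_area(hole.coords)
    return total


def _densify_xy(xy: np.ndarray, points_per_edge: int) -> np.ndarray:
    out = []
    for i in range(len(xy) - 1):
        ts = np.linspace(0.0, 1.0, points_per_edge + 2)[:-1]
        out.append(xy[i] + (xy[i + 1] - xy[i]) * ts[:, None])
    out.append(xy[-1:])
    return np.concatenate(out, axis=0)


# ----------------------------------------------------------------------
@dataclass
class ClassedPolygonSet:
    """Polygons labeled by class, in one CRS, with dissolved areas."""
    polygons: list          # list of (class label, shapely geometry)
    crs: CRS = field(default_factory=CRS.geographic)
    class_areas_km2: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def classes(self):
        return list(dict.fromkeys(lbl for lbl, _ in self.polygons))


@dataclass
class IntersectionRecord:
    """One nonempty (cell, class) overlap with its geodesic area."""
    hid: int
    klass: object
    area_km2: float
    fraction: float
    geometry: object = None


@dataclass
class VerificationReport:
    """Outcome of the three integrity checks."""
    containment_failures: list
    conservation: dict        # class -> (source km2, intersected km2, rel err)
    fraction_violations: list
    conservation_tol: float = 1e-6

    @property
    def passed(self) -> bool:
        return (not self.containment_failures
                and not self.fraction_violations
                and all(abs(err) <= self.conservation_tol
                        for _, _, err in self.conservation.values()))


# ----------------------------------------------------------------------
def dissolve(pset: ClassedPolygonSet, by_class: bool = True) -> ClassedPolygonSet:
    """Remove interior boundaries: union per class (or globally).

    Global dissolve assigns the single class label ``1``.  Dissolved
    geodesic areas per class are recorded.
    """
    groups: dict = {}
    for lbl, geom in pset.polygons:
        key = lbl if by_class else 1
        groups.setdefault(key, []).append(geom)
    out = []
    areas = {}
    for key, geoms in groups.items():
        merged = unary_union(geoms)
        out.append((key, merged))
        areas[key] = geodesic_geom_area_km2(merged, pset.crs)
    return ClassedPolygonSet(out, pset.crs, areas, list(pset.flags))


def validate_simple_features(pset: ClassedPolygonSet,
                             repair: bool = True) -> ClassedPolygonSet:
    """OGC simple-feature validity check with optional single-pass repair.

    Valid geometries pass through untouched.  Invalid ones are repaired
    with :func:`shapely.make_valid` (zero-width-buffer equivalent) and
    flagged ``repaired``; geometries that remain invalid or lose their
    polygonal character are flagged ``excluded`` and dropped.
    """
    out = []
    flags = list(pset.flags)
    for lbl, geom in pset.polygons:
        if geom.is_valid:
            out.append((lbl, geom))
            continue
        if not repair:
            flags.append(("invalid", lbl, shapely.is_valid_reason(geom)))
            continue
        fixed = shapely.make_valid(geom)
        if isinstance(fixed, GeometryCollection):
            polys = [g for g in fixed.geoms
                     if isinstance(g, (Polygon, MultiPolygon))]
            fixed = unary_union(polys) if polys else None
        if fixed is not None and not fixed.is_empty and fixed.is_valid \
                and isinstance(fixed, (Polygon, MultiPolygon)):
            flags.append(("repaired", lbl, shapely.is_valid_reason(geom)))
            out.append((lbl, fixed))
        else:
            flags.append(("excluded", lbl, shapely.is_valid_reason(geom)))
    areas = {lbl: geodesic_geom_area_km2(g, pset.crs) for lbl, g in out}
    return ClassedPolygonSet(out, pset.crs, areas, flags)


# ----------------------------------------------------------------------
def _split_antimeridian(lon, lat):
    """Wrap an unwrapped lon array into polygons split at +-180."""
    # lon came unwrapped relative to the cell centroid; shift into a
    # window and split where it leaves [-180, 180]
    if lon.min() >= -180.0 and lon.max() <= 180.0:
        return [Polygon(np.stack([lon, lat], axis=1))]
    parts = []
    for shift in (0.0, 360.0, -360.0):
        l2 = lon + shift
        poly = Polygon(np.stack([l2, lat], axis=1))
        clip = box(-180.0, -90.0, 180.0, 90.0)
        piece = poly.intersection(clip)
        if not piece.is_empty:
            parts.append(piece)
    return parts


def cell_polygons(resolution: int, crs: CRS | None = None,
                  hid_range=None, hids=None,
                  mode: str = "analytic",
                  densify_per_edge: int = 50,
                  staircase_pixel_deg: float = 1 / 120.0,
                  grid: ISEA3HGrid | None = None,
                  split_antimeridian: bool = True) -> ClassedPolygonSet:
    """Cell polygons in a source CRS, labeled by HID.

    ``analytic`` mode inverse-projects the true (densified) cell
    boundaries; ``pixel_staircase`` polygonizes an HID raster at
    ``staircase_pixel_deg`` resolution, replicating the fidelity of
    raster-polygonization workflows.  Output may be limited to an HID
    range or an explicit HID list.  Geodesic cell areas are recorded as
    class areas.
    """
    grid = grid or ISEA3HGrid()
    crs = crs or CRS.geographic()
    N = cell_count(resolution, grid.spec)
    if hids is None:
        lo, hi = (1, N) if hid_range is None else hid_range
        hids = range(max(1, lo), min(N, hi) + 1)
    out = []
    areas = {}
    if mode == "analytic":
        for hid in hids:
            geom_cell = grid.cell_geometry(hid, resolution, densify_per_edge)
            lat = geom_cell.boundary[:, 0]
            lon = geom_cell.boundary[:, 1]
            if crs.is_geographic:
                if split_antimeridian:
                    parts = _split_antimeridian(lon, lat)
                    geom = unary_union(parts)
                else:
                    geom = Polygon(np.stack([lon, lat], axis=1))
            else:
                x, y = crs.from_lonlat(lon, lat)
                geom = Polygon(np.stack([x, y], axis=1))
            out.append((hid, geom))
            areas[hid] = geodesic_geom_area_km2(geom, crs)
    elif mode == "pixel_staircase":
        hset = set(int(h) for h in hids)
        bounds = _latlon_window(grid, list(hset), resolution)
        out, areas = _staircase_polygons(grid, hset, resolution,
                                         staircase_pixel_deg, bounds, crs)
    else:
        raise ValueError("mode must be 'analytic' or 'pixel_staircase'")
    return ClassedPolygonSet(out, crs, areas)


def _latlon_window(grid, hids, resolution):
    lat, lon = grid.centroid(np.asarray(hids), resolution)
    pad = 3.0 * grid.centroid_spacing_km(resolution) / 111.0
    return (max(-90.0, lat.min() - pad), min(90.0, lat.max() + pad),
            lon.min() - pad, lon.max() + pad)


def _staircase_polygons(grid, hset, resolution, pix, bounds, crs):
    lat0, lat1, lon0, lon1 = bounds
    nr = max(2, int(round((lat1 - lat0) / pix)))
    nc = max(2, int(round((lon1 - lon0) / pix)))
    transform = Affine.from_origin(lon0, lat1, pix, pix)
    tile = RasterTile(np.zeros((nr, nc)), transform, CRS.geographic())
    ht = build_hid_tile(tile, resolution, grid)
    out, areas = [], {}
    for hid in sorted(hset):
        rows, cols = np.nonzero(ht.hids == hid)
        if len(rows) == 0:
            continue
        boxes = []
        for r0 in np.unique(rows):
            cs = np.sort(cols[rows == r0])
            breaks = np.nonzero(np.diff(cs) > 1)[0]
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(cs) - 1]])
            for s, e in zip(starts, ends):
                x0, y1 = transform * (cs[s], r0)
                x1, y0 = transform * (cs[e] + 1.0, r0 + 1.0)
                boxes.append(box(x0, y0, x1, y1))
        geom = unary_union(boxes)
        out.append((hid, geom))
        areas[hid] = geodesic_geom_area_km2(geom, crs)
    return out, areas


# ----------------------------------------------------------------------
def intersect(cells: ClassedPolygonSet, classes: ClassedPolygonSet,
              keep_geometry: bool = True) -> list:
    """Overlay cells with class polygons: one record per nonempty overlap.

    Fractions are geodesic overlap area over geodesic cell area.
    """
    if cells.crs != classes.crs:
        raise ValueError("cells and classes must share a CRS")
    cell_geoms = [g for _, g in cells.polygons]
    cell_hids = [h for h, _ in cells.polygons]
    tree = STRtree(cell_geoms)
    records = []
    for lbl, cgeom in classes.polygons:
        for idx in sorted(tree.query(cgeom)):
            piece = cell_geoms[idx].intersection(cgeom)
            if piece.is_empty:
                continue
            area = geodesic_geom_area_km2(piece, cells.crs)
            if area <= 0.0:
                continue
            hid = cell_hids[idx]
            cell_area = cells.class_areas_km2[hid]
            records.append(IntersectionRecord(
                hid=hid, klass=lbl, area_km2=area,
                fraction=area / cell_area,
                geometry=piece if keep_geometry else None))
    records.sort(key=lambda rec: (str(rec.klass), rec.hid))
    return records


def verify(records, cells: ClassedPolygonSet, classes: ClassedPolygonSet,
           conservation_tol: float = 1e-6,
           containment_buffer_deg: float = 1e-9,
           min_ring_coords: int = 4) -> VerificationReport:
    """The three integrity checks of the production workflow.

    (1) every intersected piece has at least ``min_ring_coords`` ring
    coordinates and is contained by its originating cell polygon (with a
    small buffer for shared boundaries); (2) per class, the total
    intersected area across all cells matches the dissolved source area
    within ``conservation_tol`` relative; (3) every fraction <= 1.
    Failures populate the report; nothing raises.
    """
    cell_geom = {h: g for h, g in cells.polygons}
    containment = []
    frac_viol = []
    sums: dict = {}
    for i, rec in enumerate(records):
        sums[rec.klass] = sums.get(rec.klass, 0.0) + rec.area_km2
        if rec.fraction > 1.0 + 1e-9:
            frac_viol.append((rec.hid, rec.klass, rec.fraction))
        if rec.geometry is not None:
            geoms = getattr(rec.geometry, "geoms", [rec.geometry])
            num = sum(len(g.exterior.coords) for g in geoms
                      if isinstance(g, Polygon))
            if num < min_ring_coords:
                containment.append((rec.hid, rec.klass, "too few vertices"))
                continue
            cell = cell_geom.get(rec.hid)
            if cell is not None and \
                    not cell.buffer(containment_buffer_deg).covers(rec.geometry):
                containment.append((rec.hid, rec.klass, "not contained"))
    conservation = {}
    for lbl, src in classes.class_areas_km2.items():
        tot = sums.get(lbl, 0.0)
        err = (tot - src) / src if src > 0 else (0.0 if tot == 0 else math.inf)
        conservation[lbl] = (src, tot, err)
    return VerificationReport(containment, conservation, frac_viol,
                              conservation_tol)


def records_to_fractions(records, legend=None):
    """Intersection records -> per-cell fraction table (pandas)."""
    import pandas as pd
    if not records:
        cols = list(legend) if legend else []
        return pd.DataFrame(columns=cols,
                            index=pd.Index([], name="HID", dtype=np.int64))
    df = pd.DataFrame([(r.hid, r.klass, r.fraction) for r in records],
                      columns=["HID", "klass", "fraction"])
    wide = df.pivot_table(index="HID", columns="klass", values="fraction",
                          aggfunc="sum", fill_value=0.0)
    if legend is not None:
        wide = wide.reindex(columns=list(legend), fill_value=0.0)
    wide.columns.name = None
    return wide


# ----------------------------------------------------------------------
def read_geojson(path, class_field: str = "class",
                 crs: CRS | None = None) -> ClassedPolygonSet:
    """Load polygon features from a GeoJSON file, labeled by a property."""
    import json
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for feat in feats:
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Polygon, MultiPolygon)):
            continue
        lbl = feat.get("properties", {}).get(class_field, 1)
        polys.append((lbl, geom))
    return ClassedPolygonSet(polys, crs or CRS.geographic())


def write_geojson(pset: ClassedPolygonSet, path,
                  class_field: str = "class") -> None:
    """Write a polygon set as a GeoJSON FeatureCollection."""
    import json
    feats = [{"type": "Feature",
              "properties": {class_field: lbl,
                             "area_km2": pset.class_areas_km2.get(lbl)},
              "geometry": mapping(geom)}
             for lbl, geom in pset.polygons]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ----------------------------------------------------------------------
def cross_resolution_index(records, from_resolution: int,
                           to_resolution: int,
                           grid: ISEA3HGrid | None = None) -> np.ndarray:
    """Candidate HIDs at an adjacent resolution, from prior-run records.

    Cells retained by an intersection at resolution r+-1 act as a spatial
    index: candidate cells at the target resolution are those whose
    centroids fall inside a retained cell, expanded by one neighbor ring
    so the result is a superset of the truly coincident set.
    """
    if abs(from_resolution - to_resolution) != 1:
        raise ValueError("resolutions must differ by exactly 1")
    grid = grid or ISEA3HGrid()
    retained = sorted({rec.hid for rec in records})
    if not retained:
        return np.empty(0, dtype=np.int64)
    retained_set = set(retained)
    N = cell_count(to_resolution, grid.spec)
    all_hids = np.arange(1, N + 1, dtype=np.int64)
    lat, lon = grid.centroid(all_hids, to_resolution)
    try:
        from ._fastlocate import locate_bulk
        parents = locate_bulk(grid, lat, lon, from_resolution)
    except ImportError:                              # pragma: no cover
        parents = grid.locate(lat, lon, from_resolution)
    inside = all_hids[np.isin(parents, list(retained_set))]
    cand = set(inside.tolist())
    for h in inside:
        cand.update(grid.neighbors(int(h), to_resolution).tolist())
    return np.array(sorted(cand), dtype=np.int64)
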