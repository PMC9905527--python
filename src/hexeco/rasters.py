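"""Raster carriers and the raster sampling workflow.

Each source raster is processed in its native coordinate reference
system.  Pixels are atomic: every pixel is assigned wholly to the cell
containing its centroid, producing an HID tile in one-to-one pixel
correspondence with the source tile.  For rasters on equal-area
(authalic) grids, per-cell class weights are plain pixel counts; for
geographic grids a companion tile of geodesic pixel areas supplies the
weights.  Tile-level aggregates (contingency tables, weighted sums) are
additive, so tiled datasets are processed tile by tile and merged.

Only two CRS families appear in the source data this toolkit emulates
(WGS84 geographic grids and sphere-based sinusoidal equal-area grids),
so a small internal registry covers them.  Raster I/O uses the
plain-text ESRI ASCII grid format with a JSON sidecar for CRS metadata.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geodesy
from .grid import ISEA3HGrid, cell_area_km2, cell_count
from .icosa import GridSpec

__all__ = [
    "Affine", "CRS", "RasterTile", "HidTile",
    "ContingencyTable", "WeightedSums",
    "read_ascii_grid", "write_ascii_grid",
    "build_hid_tile", "build_area_tile", "crosstab_discrete",
    "accumulate_weighted", "stat_centroid", "stat_fraction",
    "stat_mode", "stat_mean",
]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Affine:
    """Six-parameter affine geotransform, GDAL order.

    Maps pixel-space ``(col, row)`` to world ``(x, y)``:
    ``x = c + a*col + b*row``, ``y = f + d*col + e*row``.
    """
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west, north, xsize, ysize) -> "Affine":
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def __mul__(self, colrow):
        col, row = colrow
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        return (self.c + self.a * col + self.b * row,
                self.f + self.d * col + self.e * row)

    def inverse(self, xy):
        x, y = xy
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("geotransform is not invertible")
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return col, row


# ----------------------------------------------------------------------
class CRS:
    """Minimal coordinate-reference registry: geographic and sinusoidal.

    ``CRS.geographic()`` is the WGS84 longitude/latitude system (units:
    degrees).  ``CRS.sinusoidal(radius_m)`` is the sphere-based sinusoidal
    equal-area projection used by MODIS-style land products (units:
    meters; default radius 6371007.181 m).
    """

    def __init__(self, kind: str, radius_m: float | None = None):
        if kind not in ("geographic", "sinusoidal"):
            raise ValueError(f"unknown CRS kind: {kind!r}")
        self.kind = kind
        self.radius_m = radius_m or 6371007.181

    @classmethod
    def geographic(cls) -> "CRS":
        return cls("geographic")

    @classmethod
    def sinusoidal(cls, radius_m: float = 6371007.181) -> "CRS":
        return cls("sinusoidal", radius_m)

    @classmethod
    def from_id(cls, crs_id: str) -> "CRS":
        s = crs_id.strip().lower()
        if s in ("epsg:4326", "wgs84", "geographic"):
            return cls.geographic()
        if s.startswith("sinusoidal"):
            parts = s.split(":")
            r = float(parts[1]) if len(parts) > 1 else 6371007.181
            return cls.sinusoidal(r)
        raise ValueError(f"unknown CRS identifier: {crs_id!r}")

    @property
    def crs_id(self) -> str:
        if self.kind == "geographic":
            return "EPSG:4326"
        return f"sinusoidal:{self.radius_m:g}"

    @property
    def is_geographic(self) -> bool:
        return self.kind == "geographic"

    @property
    def is_equal_area(self) -> bool:
        return self.kind == "sinusoidal"

    def to_lonlat(self, x, y):
        if self.kind == "geographic":
            return np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        R = self.radius_m
        lat = np.degrees(np.asarray(y, dtype=float) / R)
        with np.errstate(divide="ignore", invalid="ignore"):
            lon = np.degrees(np.asarray(x, dtype=float)
                             / (R * np.cos(np.radians(lat))))
        return lon, lat

    def from_lonlat(self, lon, lat):
        if self.kind == "geographic":
            return np.asarray(lon, dtype=float), np.asarray(lat, dtype=float)
        R = self.radius_m
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (R * np.radians(lon) * np.cos(np.radians(lat)),
                R * np.radians(lat))

    def __eq__(self, other):
        return isinstance(other, CRS) and self.crs_id == other.crs_id


# ----------------------------------------------------------------------
@dataclass
class RasterTile:
    """In-memory raster: value array + geotransform + CRS + nodata.

    ``authalic`` marks grids whose pixels are equal-area on the Earth's
    surface (then pixel counts are valid area weights).
    """
    values: np.ndarray
    transform: Affine
    crs: CRS = field(default_factory=CRS.geographic)
    nodata: float | None = None
    authalic: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        det = self.transform.a * self.transform.e \
            - self.transform.b * self.transform.d
        if det == 0:
            raise ValueError("geotransform is not invertible")

    @property
    def shape(self):
        return self.values.shape

    def pixel_centroids_lonlat(self):
        """(lon, lat) arrays of all pixel centroids (same shape as values)."""
        nr, nc = self.values.shape
        cols, rows = np.meshgrid(np.arange(nc) + 0.5, np.arange(nr) + 0.5)
        x, y = self.transform * (cols, rows)
        return self.crs.to_lonlat(x, y)

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) pixels."""
        v = self.values
        ok = np.isfinite(v) if np.issubdtype(v.dtype, np.floating) \
            else np.ones(v.shape, dtype=bool)
        if self.nodata is not None:
            ok &= v != self.nodata
        return ok

    def sample_lonlat(self, lon, lat):
        """Pixel values at geographic points; nodata/outside -> nan."""
        x, y = self.crs.from_lonlat(lon, lat)
        col, row = self.transform.inverse((x, y))
        col = np.floor(np.atleast_1d(col)).astype(np.int64)
        row = np.floor(np.atleast_1d(row)).astype(np.int64)
        nr, nc = self.values.shape
        inside = (col >= 0) & (col < nc) & (row >= 0) & (row < nr)
        out = np.full(col.shape, np.nan)
        vals = self.values[row[inside], col[inside]].astype(float)
        if self.nodata is not None:
            vals[vals == self.nodata] = np.nan
        out[inside] = vals
        return out


@dataclass
class HidTile:
    """Per-pixel ISEA3H cell ids, aligned one-to-one with a source tile."""
    hids: np.ndarray
    resolution: int
    transform: Affine
    crs: CRS


def _check_aligned(a, b):
    if a.shape != (b.hids.shape if isinstance(b, HidTile) else b.shape):
        raise ValueError("tiles are not pixel-aligned")


# ----------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII grid + JSON sidecar)
# ----------------------------------------------------------------------

def write_ascii_grid(tile: RasterTile, path) -> None:
    """Write an ESRI ASCII grid (requires a north-up, square-pixel grid)."""
    path = Path(path)
    t = tile.transform
    if t.b or t.d or t.e >= 0 or not math.isclose(t.a, -t.e):
        raise ValueError("ASCII grid requires north-up square pixels")
    nr, nc = tile.values.shape
    nodata = tile.nodata if tile.nodata is not None else -9999
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\n")
        fh.write(f"xllcorner {t.c!r}\nyllcorner {t.f + t.e * nr!r}\n")
        fh.write(f"cellsize {t.a!r}\nNODATA_value {nodata!r}\n")
        v = np.where(tile.mask(), tile.values, nodata)
        np.savetxt(fh, v, fmt="%.10g")
    sidecar = {"crs": tile.crs.crs_id, "authalic": tile.authalic}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_ascii_grid(path) -> RasterTile:
    path = Path(path)
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nc, nr = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nr, nc):
        raise ValueError("ASCII grid shape mismatch")
    cs = header["cellsize"]
    transform = Affine.from_origin(header["xllcorner"],
                                   header["yllcorner"] + cs * nr, cs, cs)
    crs = CRS.geographic()
    authalic = False
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        crs = CRS.from_id(meta.get("crs", "EPSG:4326"))
        authalic = bool(meta.get("authalic", False))
    return RasterTile(values, transform, crs,
                      nodata=header.get("nodata_value"), authalic=authalic)


# ----------------------------------------------------------------------
# workflow operations
# ----------------------------------------------------------------------

def build_hid_tile(tile: RasterTile, resolution: int,
                   grid: ISEA3HGrid | None = None) -> HidTile:
    """Assign every pixel to a cell by its centroid (no pixel unassigned)."""
    grid = grid or ISEA3HGrid()
    lon, lat = tile.pixel_centroids_lonlat()
    lat = np.clip(lat, -90.0, 90.0)
    try:
        from ._fastlocate import locate_bulk
        hids = locate_bulk(grid, lat.ravel(), lon.ravel(), resolution)
    except ImportError:                              # pragma: no cover
        hids = grid.locate(lat.ravel(), lon.ravel(), resolution)
    return HidTile(hids.reshape(tile.values.shape), resolution,
                   tile.transform, tile.crs)


def build_area_tile(tile: RasterTile) -> RasterTile:
    """Companion tile of geodesic pixel areas (km^2) on WGS84.

    For authalic grids all pixels already share one surface area; a
    constant tile is returned with a warning.
    """
    nr, nc = tile.values.shape
    if tile.authalic or tile.crs.is_equal_area:
        warnings.warn("authalic grid: returning constant pixel areas")
        t = tile.transform
        area = abs(t.a * t.e - t.b * t.d) * 1e-6  # m^2 -> km^2
        values = np.full((nr, nc), area)
    else:
        rows = np.arange(nr)
        col_areas = geodesy.pixel_area_km2(tile.transform,
                                           np.repeat(rows, 1), np.zeros(nr))
        # geographic north-up grids: area depends on row only
        if not (tile.transform.b or tile.transform.d):
            values = np.tile(col_areas[:, None], (1, nc))
        else:
            cols, rr = np.meshgrid(np.arange(nc), rows)
            values = geodesy.pixel_area_km2(tile.transform, rr, cols)
    return RasterTile(values, tile.transform, tile.crs, nodata=None,
                      authalic=tile.authalic)


class ContingencyTable:
    """Additive per-(cell, class) weights from discrete rasters.

    Weights are pixel counts on authalic grids and geodesic pixel areas
    (km^2) otherwise.  Tables merge by addition, so tiled datasets can be
    accumulated tile by tile in any order.
    """

    def __init__(self, weights: pd.Series | None = None):
        if weights is None:
            idx = pd.MultiIndex.from_arrays([[], []], names=["hid", "klass"])
            weights = pd.Series([], index=idx, dtype=float)
        self.weights = weights

    def merge(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.weights.add(other.weights, fill_value=0.0))

    def __add__(self, other):
        return self.merge(other)

    def total_per_hid(self) -> pd.Series:
        return self.weights.groupby(level="hid").sum()


def crosstab_discrete(source: RasterTile, hids: HidTile,
                      areas: RasterTile | None = None) -> ContingencyTable:
    """Tally class weights per cell for one tile.

    On authalic grids the weight of a (cell, class) pair is its pixel
    count; otherwise each retained pixel contributes its geodesic area
    (``areas`` tile required).  Nodata pixels contribute nothing.
    """
    _check_aligned(source.values, hids)
    authalic = source.authalic or source.crs.is_equal_area
    if not authalic and areas is None:
        raise ValueError("non-authalic grid requires an area tile")
    ok = source.mask()
    h = hids.hids[ok]
    k = source.values[ok]
    if authalic:
        w = np.ones(h.shape)
    else:
        _check_aligned(areas.values, hids)
        w = areas.values[ok].astype(float)
    df = pd.DataFrame({"hid": h, "klass": k, "w": w})
    ser = df.groupby(["hid", "klass"])["w"].sum()
    return ContingencyTable(ser)


@dataclass
class WeightedSums:
    """Additive per-cell sums for the area-weighted mean.

    Holds, for each cell, the numerator ``sum(w_i * x_i)`` and the
    denominator ``sum(w_i)`` of the weighted-mean equation, with ``w_i``
    the area and ``x_i`` the value of each of the ``n`` pixels assigned
    to the cell.
    """
    sum_wx: pd.Series
    sum_w: pd.Series

    @classmethod
    def empty(cls):
        return cls(pd.Series(dtype=float), pd.Series(dtype=float))

    def merge(self, other: "WeightedSums") -> "WeightedSums":
        return WeightedSums(self.sum_wx.add(other.sum_wx, fill_value=0.0),
                            self.sum_w.add(other.sum_w, fill_value=0.0))

    def __add__(self, other):
        return self.merge(other)


def accumulate_weighted(source: RasterTile, hids: HidTile,
                        areas: RasterTile | None = None) -> WeightedSums:
    """Per-cell weighted sums from one continuous tile."""
    _check_aligned(source.values, hids)
    authalic = source.authalic or source.crs.is_equal_area
    if not authalic and areas is None:
        raise ValueError("non-authalic grid requires an area tile")
    ok = source.mask()
    h = hids.hids[ok]
    x = source.values[ok].astype(float)
    w = np.ones(x.shape) if authalic else areas.values[ok].astype(float)
    df = pd.DataFrame({"hid": h, "wx": w * x, "w": w})
    gb = df.groupby("hid")
    return WeightedSums(gb["wx"].sum(), gb["w"].sum())


# ----------------------------------------------------------------------
# statistic finalization
# ----------------------------------------------------------------------

def stat_centroid(tile: RasterTile, hids, resolution: int,
                  grid: ISEA3HGrid | None = None,
                  null_value: float = -100.0) -> pd.Series:
    """Source value at each cell centroid; nodata/outside -> null flag."""
    grid = grid or ISEA3HGrid()
    hids = np.asarray(hids, dtype=np.int64)
    lat, lon = grid.centroid(hids, resolution)
    vals = tile.sample_lonlat(lon, lat)
    vals = np.where(np.isnan(vals), null_value, vals)
    return pd.Series(vals, index=pd.Index(hids, name="HID"))


def stat_fraction(table: ContingencyTable, resolution: int, legend,
                  grid_spec: GridSpec | None = None,
                  max_overshoot: float = 0.02) -> pd.DataFrame:
    """Per-cell area fraction of each legend class.

    The denominator is the theoretical cell area (5/6 of it for the
    twelve pentagons), so sources clipped to land yield partial coverage.
    One column per legend class, in legend order, even for classes absent
    from the data.  For authalic grids convert counts to areas first with
    :func:`counts_to_area_weights`.

    Because pixels are atomic, per-cell totals fluctuate around the cell
    area by a boundary-noise term that grows with the pixel:cell size
    ratio; totals beyond ``1 + max_overshoot`` raise an integrity error.
    """
    spec = grid_spec or GridSpec()
    w = table.weights
    if len(w) == 0:
        return pd.DataFrame(columns=list(legend),
                            index=pd.Index([], name="HID", dtype=np.int64))
    wide = w.unstack("klass", fill_value=0.0)
    wide = wide.reindex(columns=list(legend), fill_value=0.0)
    hids = wide.index.to_numpy(dtype=np.int64)
    denom = np.where(hids <= 12,
                     cell_area_km2(resolution, True, spec),
                     cell_area_km2(resolution, False, spec))
    frac = wide.to_numpy() / denom[:, None]
    out = pd.DataFrame(frac, columns=list(legend),
                       index=pd.Index(hids, name="HID"))
    if (out.to_numpy() > 1.0 + max_overshoot).any():
        raise ValueError("class fraction exceeds unity: integrity error")
    return out


def counts_to_area_weights(table: ContingencyTable,
                           pixel_area_km2: float) -> ContingencyTable:
    """Convert pixel-count weights to areas for an authalic grid."""
    return ContingencyTable(table.weights * pixel_area_km2)


def stat_mode(fractions: pd.DataFrame, threshold: float = 0.2,
              null_value=-1) -> pd.Series:
    """Dominant class per cell, subject to a total-coverage threshold.

    The class with the largest fraction wins; ties break to the class
    earliest in legend (column) order.  Cells whose fractions sum below
    ``threshold`` receive the null flag.
    """
    if fractions.empty:
        return pd.Series(dtype=object,
                         index=pd.Index([], name="HID", dtype=np.int64))
    vals = fractions.to_numpy()
    best = np.argmax(vals, axis=1)          # first max wins ties
    mode = np.asarray(fractions.columns.to_numpy())[best]
    total = vals.sum(axis=1)
    out = pd.Series(mode, index=fractions.index)
    out[total < threshold] = null_value
    return out


def stat_mean(sums: WeightedSums, null_value: float = -1000.0) -> pd.Series:
    """Area-weighted mean ``sum(w x) / sum(w)``; zero-weight cells -> null."""
    den = sums.sum_w
    num = sums.sum_wx.reindex(den.index, fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / den
    mean[den <= 0] = null_value
    mean.index.name = "HID"
    return mean
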