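"""Synthetic, download-free stand-ins for the source datasets.

Everything here is synthetic and fully determined by ``(seed, config)``:
climate fields on WGS84 geographic grids (zonal cosine law plus seeded
noise, optionally clipped like land-only products), categorical cover on
geographic or equal-area grids (seeded Voronoi-style patches or i.i.d.
mixtures), and species-range polygons with sparse vertices (optionally
fragmented).  These emulate the *structure* of WorldClim-, MODIS- and
IUCN-like inputs -- grids, legends, clipping, vertex sparsity -- not
their spatial covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .icosa import latlon_to_xyz
from .rasters import CRS, Affine, RasterTile
from .vectors import ClassedPolygonSet

__all__ = ["FixtureConfig", "make_climate_raster", "make_cover_raster",
           "make_species_ranges"]


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic generators (same seed, same fixtures).

    The defaults describe a mid-size study window at 0.05-degree
    resolution with a 30 C equator-to-pole cosine temperature law and
    noise-free values (sigma = 0), so closed-form checks are exact.
    """
    seed: int = 42
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    pixel_deg: float = 0.05
    #: climate field law T = amplitude * cos(lat) + offset + N(0, sigma)
    amplitude: float = 30.0
    offset: float = 0.0
    sigma: float = 0.0
    nodata: float = -9999.0
    mask_fraction: float = 0.0
    #: categorical legend and mixture; patch_nuclei = 0 -> i.i.d. pixels
    legend: tuple = ("A", "B", "C")
    mixture: tuple | None = None
    patch_nuclei: int = 200
    #: species-range band and fragmentation
    band_lat_min: float = 0.0
    band_lat_max: float = 60.0
    band_lon_min: float = -180.0
    band_lon_max: float = 180.0
    fragments: int = 1
    gap_fraction: float = 0.25

    def grid_shape(self):
        nr = int(round((self.lat_max - self.lat_min) / self.pixel_deg))
        nc = int(round((self.lon_max - self.lon_min) / self.pixel_deg))
        return nr, nc

    def transform(self) -> Affine:
        return Affine.from_origin(self.lon_min, self.lat_max,
                                  self.pixel_deg, self.pixel_deg)


def make_climate_raster(cfg: FixtureConfig) -> RasterTile:
    """WGS84 geographic grid with a zonal cosine field plus seeded noise.

    If ``mask_fraction`` > 0 the southernmost share of rows is set to
    nodata, emulating a product clipped to part of the globe; the masked
    share matches the request to within one pixel row.
    """
    nr, nc = cfg.grid_shape()
    rng = np.random.default_rng(cfg.seed)
    lats = cfg.lat_max - (np.arange(nr) + 0.5) * cfg.pixel_deg
    vals = cfg.amplitude * np.cos(np.radians(lats))[:, None] + cfg.offset \
        + np.zeros((nr, nc))
    if cfg.sigma > 0:
        vals = vals + rng.normal(0.0, cfg.sigma, size=(nr, nc))
    if cfg.mask_fraction > 0:
        k = int(round(cfg.mask_fraction * nr))
        if k:
            vals[nr - k:, :] = cfg.nodata
    return RasterTile(vals, cfg.transform(), CRS.geographic(),
                      nodata=cfg.nodata)


def make_cover_raster(cfg: FixtureConfig, crs: CRS | None = None) -> RasterTile:
    """Seeded categorical cover with controllable patch scale.

    With ``patch_nuclei`` > 0, classes form Voronoi patches around
    uniformly seeded nuclei (patch scale shrinks as nuclei grow); with
    ``patch_nuclei = 0`` every pixel draws its class i.i.d. from the
    mixture.  Classes are stored as integer legend indices.
    """
    if not cfg.legend:
        raise ValueError("legend must be nonempty")
    crs = crs or CRS.geographic()
    if not crs.is_geographic:
        raise NotImplementedError("cover fixtures are generated geographic")
    nr, nc = cfg.grid_shape()
    rng = np.random.default_rng(cfg.seed + 1)
    k = len(cfg.legend)
    mix = np.full(k, 1.0 / k) if cfg.mixture is None \
        else np.asarray(cfg.mixture, dtype=float)
    mix = mix / mix.sum()
    if k == 1:
        classes = np.zeros((nr, nc), dtype=np.int64)
    elif cfg.patch_nuclei <= 0:
        classes = rng.choice(k, size=(nr, nc), p=mix)
    else:
        z = rng.uniform(-1.0, 1.0, cfg.patch_nuclei)
        lon_n = rng.uniform(-180.0, 180.0, cfg.patch_nuclei)
        lat_n = np.degrees(np.arcsin(z))
        nuc_class = rng.choice(k, size=cfg.patch_nuclei, p=mix)
        tree = cKDTree(latlon_to_xyz(lat_n, lon_n))
        lats = cfg.lat_max - (np.arange(nr) + 0.5) * cfg.pixel_deg
        lons = cfg.lon_min + (np.arange(nc) + 0.5) * cfg.pixel_deg
        gl, gt = np.meshgrid(lons, lats)
        _, idx = tree.query(latlon_to_xyz(gt.ravel(), gl.ravel()))
        classes = nuc_class[idx].reshape(nr, nc)
    return RasterTile(classes, cfg.transform(), crs, nodata=-1)


def make_species_ranges(cfg: FixtureConfig, species=("synthetic_sp",)
                        ) -> ClassedPolygonSet:
    """Latitude-band range polygons with sparse vertices.

    Each species receives ``fragments`` disjoint longitude slices of the
    band (one contiguous slice if ``fragments`` is 1), with corners only
    -- no densification -- so the straight-in-CRS edge rule matters.
    Successive species are shifted in longitude deterministically.
    """
    if not (-90.0 <= cfg.band_lat_min < cfg.band_lat_max <= 90.0):
        raise ValueError("band latitudes must be ordered within [-90, 90]")
    if cfg.fragments < 1:
        raise ValueError("fragments must be >= 1")
    polys = []
    span = cfg.band_lon_max - cfg.band_lon_min
    width = span / cfg.fragments
    fill = width * (1.0 - cfg.gap_fraction) if cfg.fragments > 1 else width
    for si, name in enumerate(species):
        shift = (si * 0.25 * span / max(len(species), 1)) % max(width - fill, 1.0) \
            if cfg.fragments > 1 else 0.0
        parts = []
        for i in range(cfg.fragments):
            lo = cfg.band_lon_min + i * width + shift
            hi = min(lo + fill, cfg.band_lon_max)
            ring = [(lo, cfg.band_lat_min), (hi, cfg.band_lat_min),
                    (hi, cfg.band_lat_max), (lo, cfg.band_lat_max)]
            parts.append(Polygon(ring))
        geom = parts[0] if len(parts) == 1 else unary_union(parts)
        polys.append((name, geom))
    return ClassedPolygonSet(polys, CRS.geographic())
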