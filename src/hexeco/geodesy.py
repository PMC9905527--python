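"""Ellipsoidal and spherical measurement utilities.

Polygon areas are computed by Green's theorem on the ellipsoid.  The area
element integrates in closed form over latitude,

    q(phi) = (b^2 / 2) [ sin phi / (1 - e^2 sin^2 phi)
                         + atanh(e sin phi) / e ],

so the area enclosed by a ring is the line integral of ``q`` over
longitude.  Ring edges are interpreted as straight lines in plate-carree
(longitude/latitude) space -- the same interpretation the vector workflow
uses for source polygons -- and the per-edge integral is evaluated by
Gauss-Legendre quadrature on subdivided segments, which is accurate to
near machine precision.  On a sphere (``flattening = 0``) the formulas
reduce to the exact spherical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .icosa import AUTHALIC_RADIUS_KM, latlon_to_xyz

__all__ = [
    "EllipsoidSpec", "WGS84", "AUTHALIC_SPHERE",
    "geodesic_polygon_area_km2", "pixel_area_km2", "area_distortion",
    "idw_interpolate", "great_circle_km",
]


@dataclass(frozen=True)
class EllipsoidSpec:
    """Reference surface for measurement: semi-major axis and flattening."""
    semi_major_m: float = 6378137.0
    flattening: float = 1.0 / 298.257223563

    def __post_init__(self):
        if not self.semi_major_m > 0:
            raise ValueError("semi_major_m must be positive")
        if not 0.0 <= self.flattening < 1.0:
            raise ValueError("flattening must lie in [0, 1)")

    @property
    def semi_minor_m(self) -> float:
        return self.semi_major_m * (1.0 - self.flattening)

    @property
    def e2(self) -> float:
        f = self.flattening
        return f * (2.0 - f)

    @property
    def total_area_km2(self) -> float:
        """Closed-form surface area: ``2 pi (q(90) - q(-90))``."""
        return 4.0 * math.pi * float(_q(np.array(90.0), self)) * 1e-6


WGS84 = EllipsoidSpec()
#: sphere with the WGS84 surface area; the grid's reference surface
AUTHALIC_SPHERE = EllipsoidSpec(AUTHALIC_RADIUS_KM * 1e3, 0.0)


def _q(lat_deg, ell: EllipsoidSpec):
    """Antiderivative of the area element over latitude, in m^2/rad."""
    phi = np.radians(np.asarray(lat_deg, dtype=float))
    s = np.sin(phi)
    b2 = ell.semi_minor_m ** 2
    e = math.sqrt(ell.e2)
    if e == 0.0:
        return b2 * s
    return 0.5 * b2 * (s / (1.0 - ell.e2 * s * s) + np.arctanh(e * s) / e)


# 8-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def geodesic_polygon_area_km2(ring, ell: EllipsoidSpec = WGS84) -> float:
    """Unsigned area (km^2) enclosed by a closed lat/lon ring.

    ``ring`` is a sequence of (lat, lon) pairs; the first and last vertex
    may coincide but need not.  Edges are straight in plate-carree space.
    Rings enclosing a pole are handled via the winding of longitude.
    Orientation does not affect the magnitude.
    """
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise ValueError("ring must be an (n, 2) array of (lat, lon)")
    if len(ring) >= 2 and np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    if len(ring) < 3:
        raise ValueError("ring needs at least 3 distinct vertices")
    # a vertex exactly at a pole has no meaningful longitude: split it into
    # two copies carrying the neighboring vertices' longitudes, so both
    # adjacent edges become meridional and the connecting run lies on the
    # (area-free) pole itself
    pole = np.abs(ring[:, 0]) >= 90.0 - 1e-12
    if pole.any():
        parts = []
        npts = len(ring)
        for i in range(npts):
            if not pole[i]:
                parts.append(ring[i])
            else:
                prev = ring[(i - 1) % npts]
                nxt = ring[(i + 1) % npts]
                parts.append([ring[i, 0], prev[1]])
                parts.append([ring[i, 0], nxt[1]])
        ring = np.asarray(parts)
    lat1, lon1 = ring[:, 0], ring[:, 1]
    lat2 = np.roll(lat1, -1)
    lon2 = np.roll(lon1, -1)
    # listed edges are literal in the (lon, lat) plane: a vertex sequence
    # that sweeps 360 degrees really does (that is how a ring encircles a
    # pole); only the implicit closing edge from the last vertex back to
    # the first is wrapped to the short way around
    dlon = lon2 - lon1
    dlon[-1] = (dlon[-1] + 180.0) % 360.0 - 180.0
    # subdivide long edges so each quadrature piece is short
    span = np.maximum(np.abs(dlon), np.abs(lat2 - lat1))
    nseg = np.maximum(1, np.ceil(span / 1.0).astype(int))
    total = 0.0
    winding = np.radians(dlon).sum()
    for i in range(len(ring)):
        k = nseg[i]
        tt = (np.arange(k)[:, None] + _GL_X[None, :]) / k
        lats = lat1[i] + (lat2[i] - lat1[i]) * tt
        q = _q(lats, ell)
        total += math.radians(dlon[i]) / k * float((q * _GL_W[None, :]).sum())
    # a ring with net longitude winding encircles a pole; correcting the
    # line integral with the q-potential of either pole yields the areas
    # of the two complementary regions -- return the smaller (for the
    # winding-free case the integral is already the signed area)
    w = round(winding / (2.0 * math.pi))
    if w == 0:
        return abs(total) * 1e-6
    qp = 2.0 * math.pi * float(_q(np.array(90.0), ell))
    return min(abs(total - w * qp), abs(total + w * qp)) * 1e-6


def pixel_area_km2(geotransform, rows, cols, ell: EllipsoidSpec = WGS84):
    """Geodesic area (km^2) of raster pixels on a geographic grid.

    ``geotransform`` maps (col, row) pixel corners to (lon, lat) as in the
    six-parameter GDAL convention (see :mod:`hexeco.rasters`); the pixel
    spanning rows ``r..r+1`` and cols ``c..c+1`` is bounded by meridians
    and parallels, so its area is ``dlon * (q(lat_top) - q(lat_bottom))``
    exactly.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    lon0, lat0 = geotransform * (cols, rows)
    lon1, lat1 = geotransform * (cols + 1.0, rows + 1.0)
    if np.any(np.maximum(np.abs(lat0), np.abs(lat1)) > 90.0 + 1e-9):
        raise ValueError("pixel extends beyond |lat| = 90")
    dlon = np.abs(np.radians(lon1 - lon0))
    return np.abs(_q(lat0, ell) - _q(lat1, ell)) * dlon * 1e-6


def area_distortion(lat_deg, radius_deg: float = 0.25,
                    ell: EllipsoidSpec = AUTHALIC_SPHERE,
                    n_vertices: int = 360):
    """Relative geodesic area of a plate-carree circle versus the equator.

    A circle of ``radius_deg`` is drawn in longitude/latitude degree space
    centered at the given latitude; its geodesic area, divided by the area
    of the same circle at latitude 0, measures the area distortion of
    equal-angle raster pixels (approximately cos(lat) on the sphere).
    The circle is clamped so it does not cross a pole.
    """
    if radius_deg <= 0:
        raise ValueError("radius_deg must be positive")
    lats = np.atleast_1d(np.asarray(lat_deg, dtype=float))
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    circ = np.stack([radius_deg * np.cos(t), radius_deg * np.sin(t)], axis=1)

    def circle_area(lat0):
        lat0 = float(np.clip(lat0, -90.0 + radius_deg, 90.0 - radius_deg))
        ring = circ + np.array([lat0, 0.0])
        return geodesic_polygon_area_km2(ring, ell)

    ref = circle_area(0.0)
    out = np.array([circle_area(l) / ref for l in lats])
    return float(out[0]) if np.isscalar(lat_deg) else out


def great_circle_km(lat1, lon1, lat2, lon2,
                    radius_km: float = AUTHALIC_RADIUS_KM):
    """Great-circle distance on the authalic sphere (km)."""
    p = latlon_to_xyz(lat1, lon1)
    q = latlon_to_xyz(lat2, lon2)
    cross = np.linalg.norm(np.cross(p, q), axis=-1)
    dot = np.einsum("...i,...i->...", p, q)
    return np.arctan2(cross, dot) * radius_km


def idw_interpolate(samples, targets, power: float = 2.0, k: int = 4,
                    radius_km: float = AUTHALIC_RADIUS_KM):
    """Inverse (geodesic) distance weighted interpolation.

    ``samples`` is an (n, 3) array-like of (lat, lon, value); ``targets``
    an (m, 2) array-like of (lat, lon) or a single (lat, lon) pair.  The
    estimate at each target is ``sum(d_i^-p v_i) / sum(d_i^-p)`` over the
    ``k`` nearest samples by great-circle distance; a target coinciding
    with a sample returns that sample's value exactly.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3 or len(samples) == 0:
        raise ValueError("samples must be a non-empty (n, 3) array")
    targets = np.asarray(targets, dtype=float)
    single = targets.ndim == 1
    targets = np.atleast_2d(targets)
    k = min(k, len(samples))

    sp = latlon_to_xyz(samples[:, 0], samples[:, 1])
    tp = latlon_to_xyz(targets[:, 0], targets[:, 1])
    tree = cKDTree(sp)
    chord, idx = tree.query(tp, k=k)
    chord = np.atleast_2d(chord.reshape(len(targets), k))
    idx = idx.reshape(len(targets), k)
    arc = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)) * radius_km
    vals = samples[idx, 2]
    exact = arc[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = arc ** (-power)
    w[~np.isfinite(w)] = 0.0
    num = (w * vals).sum(axis=1)
    den = w.sum(axis=1)
    out = np.where(exact, vals[:, 0],
                   num / np.where(den > 0, den, 1.0))
    return float(out[0]) if single else out
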