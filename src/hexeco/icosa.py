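"""Oriented icosahedron geometry underlying the ISEA3H grid.

The grid is generated from a regular icosahedron inscribed in the authalic
sphere.  Its orientation is given by the position of one vertex (the
"pole" vertex) and the azimuth from that vertex to one of its five
neighbors.  The default orientation is the de-facto standard used by
reference DGGS software: vertex at 58.28252559 N, 11.25 E, azimuth 0,
which places all twelve vertices in ocean and makes the grid symmetric
about the equator (four vertices lie exactly on it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: Authalic Earth radius in km (sphere with the same surface area as WGS84).
AUTHALIC_RADIUS_KM = 6371.0071809

#: Latitude of the upper vertex ring of a pole-oriented icosahedron, deg.
_RING_LAT_DEG = math.degrees(math.atan(0.5))


@dataclass(frozen=True)
class GridSpec:
    """Parameterization of the ISEA3H grid.

    Attributes
    ----------
    earth_radius_km:
        Radius of the authalic sphere the grid lives on.
    pole_lat_deg, pole_lon_deg:
        Position of icosahedron vertex 0.
    azimuth_deg:
        Azimuth (clockwise from north) from vertex 0 to vertex 1.
    max_resolution:
        Largest grid resolution this spec supports.
    """

    earth_radius_km: float = AUTHALIC_RADIUS_KM
    pole_lat_deg: float = 58.28252559
    pole_lon_deg: float = 11.25
    azimuth_deg: float = 0.0
    max_resolution: int = 12

    def __post_init__(self) -> None:
        if not self.earth_radius_km > 0:
            raise ValueError("earth_radius_km must be positive")
        if not -90.0 <= self.pole_lat_deg <= 90.0:
            raise ValueError("pole_lat_deg must lie in [-90, 90]")
        if not -180.0 < self.pole_lon_deg <= 180.0:
            raise ValueError("pole_lon_deg must lie in (-180, 180]")
        if not 0 <= self.max_resolution:
            raise ValueError("max_resolution must be non-negative")


def latlon_to_xyz(lat_deg, lon_deg):
    """Unit vectors from geographic coordinates (degrees)."""
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    cl = np.cos(lat)
    return np.stack([cl * np.cos(lon), cl * np.sin(lon), np.sin(lat)], axis=-1)


def xyz_to_latlon(xyz):
    """Geographic coordinates (degrees) from unit vectors."""
    xyz = np.asarray(xyz, dtype=float)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    lat = np.degrees(np.arctan2(z, np.hypot(x, y)))
    lon = np.degrees(np.arctan2(y, x))
    return lat, lon


def _rot_z(angle):
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle):
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _azimuth_at(p, q):
    """Compass azimuth (radians, clockwise from north) of q seen from p."""
    z = np.array([0.0, 0.0, 1.0])
    north = z - np.dot(z, p) * p
    east = np.cross(z, p)
    d = q - np.dot(q, p) * p
    return math.atan2(np.dot(d, east), np.dot(d, north))


class Icosahedron:
    """Vertices, faces, tangent frames and unfold maps for one orientation.

    Faces are indexed 0..19; within each face the three corners occupy the
    planar azimuths 0, 120 and 240 degrees around the face center (measured
    clockwise from the tangent-north at the center, offset so that the
    lowest-numbered vertex of the face sits at planar azimuth 0).
    """

    #: vertex triples per face (pole vertex 0, upper ring 1-5 at pole-frame
    #: longitudes 0,72,...; lower ring 6-10 at 36,108,...; vertex 11 opposite)
    FACES = (
        (0, 1, 2), (0, 2, 3), (0, 3, 4), (0, 4, 5), (0, 5, 1),
        (1, 2, 6), (2, 3, 7), (3, 4, 8), (4, 5, 9), (5, 1, 10),
        (2, 6, 7), (3, 7, 8), (4, 8, 9), (5, 9, 10), (1, 10, 6),
        (6, 7, 11), (7, 8, 11), (8, 9, 11), (9, 10, 11), (10, 6, 11),
    )

    def __init__(self, spec: GridSpec):
        self.spec = spec
        self.vertices = self._build_vertices(spec)        # (12, 3)
        self._build_faces()
        self._build_edges()

    # ------------------------------------------------------------------
    @staticmethod
    def _build_vertices(spec: GridSpec) -> np.ndarray:
        ring = _RING_LAT_DEG
        lats = [90.0] + [ring] * 5 + [-ring] * 5 + [-90.0]
        lons = [0.0] + [72.0 * k for k in range(5)] + \
               [36.0 + 72.0 * k for k in range(5)] + [0.0]
        base = latlon_to_xyz(lats, lons)

        colat = math.radians(90.0 - spec.pole_lat_deg)
        lon0 = math.radians(spec.pole_lon_deg)
        az0 = math.radians(spec.azimuth_deg)

        def orient(psi, c):
            m = _rot_z(lon0) @ _rot_y(c) @ _rot_z(psi)
            return base @ m.T

        # changing psi rotates every vertex rigidly about vertex 0, so the
        # azimuth to vertex 1 responds exactly linearly (+-psi); calibrate
        # at a slightly tilted proxy when vertex 0 sits on a pole, where
        # the azimuth itself is degenerate (the psi limit is continuous)
        cal = min(max(colat, 1e-7), math.pi - 1e-7)
        v = orient(0.0, cal)
        resid = _azimuth_at(v[0], v[1]) - az0
        for psi in (-resid, resid):
            v = orient(psi, cal)
            err = (_azimuth_at(v[0], v[1]) - az0 + math.pi) \
                % (2 * math.pi) - math.pi
            if abs(err) < 1e-6:
                return orient(psi, colat)
        raise RuntimeError("failed to calibrate icosahedron azimuth")

    # ------------------------------------------------------------------
    def _build_faces(self) -> None:
        V = self.vertices
        nf = len(self.FACES)
        centers = np.empty((nf, 3))
        for i, f in enumerate(self.FACES):
            c = V[list(f)].sum(axis=0)
            centers[i] = c / np.linalg.norm(c)
        self.face_centers = centers

        z = np.array([0.0, 0.0, 1.0])
        north = z - centers * centers[:, 2:3]
        north /= np.linalg.norm(north, axis=1, keepdims=True)
        east = np.cross(np.broadcast_to(z, centers.shape), centers)
        east /= np.linalg.norm(east, axis=1, keepdims=True)
        self.face_north = north
        self.face_east = east

        # spherical angle face center -> vertex (identical for all faces)
        self.g = math.acos(float(np.clip(np.dot(centers[0], V[0]), -1, 1)))

        # reference azimuth of each face = azimuth of its lowest vertex;
        # corner_vertex[i, k] = vertex id at planar azimuth 120k degrees
        self.az_ref = np.empty(nf)
        self.corner_vertex = np.empty((nf, 3), dtype=np.int64)
        for i, f in enumerate(self.FACES):
            ref = min(f)
            c, n, e = centers[i], north[i], east[i]

            def az_of(vid):
                d = V[vid] - np.dot(V[vid], c) * c
                return math.atan2(np.dot(d, e), np.dot(d, n))

            a0 = az_of(ref)
            self.az_ref[i] = a0
            for vid in f:
                rel = (az_of(vid) - a0) % (2 * math.pi)
                k = int(round(rel / (2 * math.pi / 3))) % 3
                self.corner_vertex[i, k] = vid
        # sanity: each face has all three corners assigned
        assert all(len(set(row)) == 3 for row in self.corner_vertex)

    # ------------------------------------------------------------------
    def _build_edges(self) -> None:
        """Global edge table and planar unfold maps between adjacent faces."""
        pairs = {}
        for i, f in enumerate(self.FACES):
            for a in range(3):
                for b in range(a + 1, 3):
                    key = tuple(sorted((f[a], f[b])))
                    pairs.setdefault(key, []).append(i)
        edges = sorted(pairs)
        assert len(edges) == 30 and all(len(v) == 2 for v in pairs.values())
        self.edges = edges
        self.edge_id = {e: i for i, e in enumerate(edges)}
        self.edge_faces = {e: tuple(sorted(pairs[e])) for e in edges}

    # ------------------------------------------------------------------
    @property
    def vertex_latlon(self):
        return xyz_to_latlon(self.vertices)


@lru_cache(maxsize=8)
def get_icosahedron(spec: GridSpec) -> Icosahedron:
    return Icosahedron(spec)
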