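"""Icosahedral Snyder equal-area (ISEA) projection, forward and inverse.

The projection maps each of the twenty spherical triangles of an oriented
icosahedron onto a planar equilateral triangle while preserving area
exactly.  The construction follows Snyder's equal-area projection for
polyhedral globes: within a face, a point is expressed by its spherical
distance ``z`` and azimuth ``Az`` from the face center; the azimuth is
folded into a 60-degree sector using the face's sixfold symmetry, mapped
through the equal-area relations, and unfolded again.

All math is done on the unit sphere; planar coordinates are in units of
the sphere radius.  Face-plane coordinates have the face center at the
origin, with the face's lowest-numbered icosahedron vertex on the
positive y axis at distance ``R' tan g``.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .icosa import GridSpec, Icosahedron, get_icosahedron, latlon_to_xyz, xyz_to_latlon

_DEG36 = math.radians(36.0)
_DEG60 = math.radians(60.0)
_DEG120 = math.radians(120.0)
_COT30 = 1.0 / math.tan(math.radians(30.0))
_S120 = math.sin(_DEG120)
_C120 = math.cos(_DEG120)
_ROT_S = np.array([0.0, _S120, -_S120])     # sin(120 j), j = 0, 1, 2
_ROT_C = np.array([1.0, _C120, _C120])      # cos(120 j)


class SnyderProjection:
    """Vectorized forward/inverse ISEA projection for one grid orientation."""

    def __init__(self, spec: GridSpec):
        self.spec = spec
        self.ico: Icosahedron = get_icosahedron(spec)
        self.g = self.ico.g                      # face center -> vertex arc
        self.tan_g = math.tan(self.g)
        self.cos_g = math.cos(self.g)
        # R' chosen so the 20 planar triangles together cover 4*pi exactly
        self.Rp = math.sqrt(4.0 * math.pi / (15.0 * math.sqrt(3.0) * self.tan_g ** 2))
        self.Rp2_tan2g = self.Rp ** 2 * self.tan_g ** 2
        #: planar distance face center -> triangle corner
        self.corner_radius = self.Rp * self.tan_g
        #: planar triangle side length
        self.side = self.corner_radius * math.sqrt(3.0)
        # planar corner positions (shared by every face): corner k at
        # planar azimuth 120k degrees, x = r sin(az), y = r cos(az)
        az = np.radians([0.0, 120.0, 240.0])
        self.corners_xy = self.corner_radius * np.stack(
            [np.sin(az), np.cos(az)], axis=1)

    # ------------------------------------------------------------------
    def find_face(self, xyz: np.ndarray) -> np.ndarray:
        """Containing face per point.

        Points on shared edges/vertices are equidistant from several face
        centers up to rounding; any face within 1e-12 of the maximum dot
        product counts as tied and the lowest face id wins.
        """
        dots = xyz @ self.ico.face_centers.T
        m = dots.max(axis=-1, keepdims=True)
        return np.argmax(dots >= m - 1e-12, axis=-1)

    # ------------------------------------------------------------------
    def forward_xyz(self, xyz: np.ndarray, face: np.ndarray | None = None):
        """Project unit vectors; returns (face_id, x, y) in face plane.

        The implementation propagates sines and cosines algebraically and
        applies the sector fold as exact 120-degree rotations, so only one
        ``arctan2`` and one ``arccos`` per point are required (the routine
        is the hot path of bulk point location).
        """
        xyz = np.atleast_2d(xyz)
        if face is None:
            face = self.find_face(xyz)
        c = self.ico.face_centers[face]
        n = self.ico.face_north[face]
        e = self.ico.face_east[face]

        dot_c = np.einsum("ij,ij->i", xyz, c)
        dn = np.einsum("ij,ij->i", xyz, n)
        de = np.einsum("ij,ij->i", xyz, e)
        sin_z = np.hypot(dn, de)
        # sin(z/2), cos(z/2) without computing z itself
        cos_half = np.sqrt(np.clip((1.0 + dot_c) * 0.5, 1e-30, None))
        sin_half = sin_z / (2.0 * cos_half)

        az = np.arctan2(de, dn) - self.ico.az_ref[face]
        az = np.mod(az, 2.0 * math.pi)
        j = np.floor(az / _DEG120)
        az_f = az - j * _DEG120
        mirror = az_f > _DEG60
        Az = np.where(mirror, _DEG120 - az_f, az_f)
        sinAz, cosAz = np.sin(Az), np.cos(Az)

        # Snyder sector relations (Az in [0, 60 deg])
        H = np.arccos(np.clip(sinAz * (math.sin(_DEG36) * self.cos_g)
                              - cosAz * math.cos(_DEG36), -1.0, 1.0))
        AG = Az + _DEG36 + H - math.pi
        # sin/cos of the planar azimuth from its atan2 arguments
        num = 2.0 * AG
        den = self.Rp2_tan2g - 2.0 * AG * _COT30
        inv = 1.0 / np.hypot(num, den)
        sin_azp = num * inv
        cos_azp = den * inv
        # sin(q/2) from cos(q) = w / hypot(tan g, w)
        wq = cosAz + sinAz * _COT30
        cos_q = wq / np.hypot(self.tan_g, wq)
        sin_half_q = np.sqrt(np.clip((1.0 - cos_q) * 0.5, 0.0, None))
        dp = self.Rp * self.tan_g / (cos_azp + sin_azp * _COT30)
        rho = dp * sin_half / sin_half_q

        # unfold: mirror (angle -> 120 deg - angle), then rotate by j * 120
        sm = _S120 * cos_azp - _C120 * sin_azp
        cm = _C120 * cos_azp + _S120 * sin_azp
        s = np.where(mirror, sm, sin_azp)
        co = np.where(mirror, cm, cos_azp)
        ji = j.astype(np.int64) % 3
        rs, rc = _ROT_S[ji], _ROT_C[ji]
        x = rho * (s * rc + co * rs)
        y = rho * (co * rc - s * rs)
        return face, x, y

    def _forward_sector(self, Az, z):
        """Snyder equal-area relations for Az in [0, 60deg]."""
        sinAz, cosAz = np.sin(Az), np.cos(Az)
        H = np.arccos(np.clip(sinAz * math.sin(_DEG36) * self.cos_g
                              - cosAz * math.cos(_DEG36), -1.0, 1.0))
        AG = Az + _DEG36 + H - math.pi
        azp = np.arctan2(2.0 * AG, self.Rp2_tan2g - 2.0 * AG * _COT30)
        q = np.arctan2(self.tan_g, cosAz + sinAz * _COT30)
        dp = self.Rp * self.tan_g / (np.cos(azp) + np.sin(azp) * _COT30)
        f = dp / (2.0 * self.Rp * np.sin(q / 2.0))
        rho = 2.0 * self.Rp * f * np.sin(z / 2.0)
        return rho, azp

    # ------------------------------------------------------------------
    def forward(self, lat_deg, lon_deg):
        """Project geographic coordinates; returns (face, x, y) arrays."""
        lat = np.asarray(lat_deg, dtype=float)
        if not np.all(np.isfinite(lat)) or not np.all(np.isfinite(np.asarray(lon_deg, dtype=float))):
            raise ValueError("coordinates must be finite")
        if np.any(np.abs(lat) > 90.0 + 1e-12):
            raise ValueError("latitude must lie in [-90, 90]")
        return self.forward_xyz(latlon_to_xyz(lat_deg, lon_deg))

    # ------------------------------------------------------------------
    def inverse_xyz(self, face, x, y):
        """Inverse projection of face-plane points to unit vectors."""
        face = np.atleast_1d(np.asarray(face, dtype=np.int64))
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        rho = np.hypot(x, y)
        azp_total = np.mod(np.arctan2(x, y), 2.0 * math.pi)
        j = np.floor(azp_total / _DEG120)
        azp_f = azp_total - j * _DEG120
        mirror = azp_f > _DEG60
        azp = np.where(mirror, _DEG120 - azp_f, azp_f)

        Az, z = self._inverse_sector(azp, rho)

        az_total = np.where(mirror, _DEG120 - Az, Az) + j * _DEG120 \
            + self.ico.az_ref[face]
        c = self.ico.face_centers[face]
        n = self.ico.face_north[face]
        e = self.ico.face_east[face]
        sz, cz = np.sin(z)[:, None], np.cos(z)[:, None]
        d = np.cos(az_total)[:, None] * n + np.sin(az_total)[:, None] * e
        out = cz * c + sz * d
        return out / np.linalg.norm(out, axis=1, keepdims=True)

    def _inverse_sector(self, azp, rho):
        """Invert the sector relations: planar (azp, rho) -> spherical."""
        t = np.tan(azp)
        AG = self.Rp2_tan2g * t / (2.0 * (1.0 + t * _COT30))
        sin36 = math.sin(_DEG36)
        cos36 = math.cos(_DEG36)
        Az = azp.copy()
        for _ in range(12):
            u = np.sin(Az) * sin36 * self.cos_g - np.cos(Az) * cos36
            u = np.clip(u, -1.0, 1.0)
            H = np.arccos(u)
            h = Az + _DEG36 + H - math.pi - AG
            up = np.cos(Az) * sin36 * self.cos_g + np.sin(Az) * cos36
            sinH = np.sqrt(np.clip(1.0 - u * u, 1e-30, None))
            dh = 1.0 - up / sinH
            step = h / np.where(np.abs(dh) < 1e-12, 1e-12, dh)
            Az = Az - step
            if np.max(np.abs(step)) < 1e-15:
                break
        Az = np.clip(Az, 0.0, _DEG60)
        q = np.arctan2(self.tan_g, np.cos(Az) + np.sin(Az) * _COT30)
        dp = self.Rp * self.tan_g / (np.cos(azp) + np.sin(azp) * _COT30)
        f = dp / (2.0 * self.Rp * np.sin(q / 2.0))
        z = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.Rp * f), -1.0, 1.0))
        return Az, z

    def inverse(self, face, x, y):
        """Inverse projection to geographic coordinates (degrees)."""
        return xyz_to_latlon(self.inverse_xyz(face, x, y))

    # ------------------------------------------------------------------
    def barycentric(self, x, y):
        """Areal coordinates of planar points w.r.t. the face triangle.

        Returns an (n, 3) array; all components >= 0 inside the triangle.
        Component k vanishes on the edge opposite corner k.
        """
        P = self.corners_xy
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.empty(x.shape + (3,))
        for k in range(3):
            a, b, c = P[k], P[(k + 1) % 3], P[(k + 2) % 3]
            # signed area coordinate for corner k
            den = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
            num = (b[0] - x) * (c[1] - y) - (c[0] - x) * (b[1] - y)
            out[..., k] = num / den
        return out


@lru_cache(maxsize=8)
def get_projection(spec: GridSpec) -> SnyderProjection:
    return SnyderProjection(spec)
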