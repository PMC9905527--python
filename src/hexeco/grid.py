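"""ISEA3H grid construction: addressing, point location, cell geometry.

Cells at resolution ``r`` are the Voronoi regions of a triangular lattice
laid over the planar faces of the Snyder-projected icosahedron.  Each face
triangle of side ``L`` carries a lattice of spacing ``L / 3^(r/2)``; at
even resolutions (class I) the lattice is aligned with the triangle edges,
at odd resolutions (class II) it is rotated 30 degrees.  Both classes
include the triangle corners, so the twelve icosahedron vertices carry
cells at every resolution; those cells are pentagons with 5/6 the hexagon
area.  Consecutive resolutions interleave: the resolution-``r+1`` lattice
consists of the resolution-``r`` cell centers plus the resolution-``r``
cell corners (the aperture-3 property), which this module exploits to
compute exact cell corners.

Cell identification numbers (HIDs) number the cells of one resolution
sequentially from 1: first the 12 pentagons (in icosahedron vertex
order), then cells centered on icosahedron edges (edge-major, positions
ordered from the lower-numbered vertex), then face-interior cells
(face-major, row-major).  The ordering is deterministic and stable; no
result of the toolkit depends on which cell receives which number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .icosa import GridSpec, get_icosahedron, latlon_to_xyz, xyz_to_latlon
from .snyder import get_projection

__all__ = [
    "GridSpec", "CellGeometry", "ISEA3HGrid",
    "cell_count", "cell_area_km2", "centroid_spacing_km",
]

#: arc length (radians) between adjacent icosahedron vertices
_EDGE_ARC = math.atan(2.0)

_STEPS = np.array([(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)],
                  dtype=np.int64)


# ----------------------------------------------------------------------
# resolution-independent quantities
# ----------------------------------------------------------------------

def cell_count(resolution: int, spec: GridSpec | None = None) -> int:
    """Number of cells at a resolution: ``10 * 3**r + 2``."""
    _check_resolution(resolution, spec)
    return 10 * 3 ** resolution + 2


def cell_area_km2(resolution: int, pentagon: bool = False,
                  spec: GridSpec | None = None) -> float:
    """Theoretical cell area on the authalic sphere.

    Hexagons measure ``4 pi R^2 / (10 * 3^r)``; the twelve pentagons 5/6 of
    that, so that ``12 * (5/6) A + (N - 12) A`` equals the sphere exactly.
    """
    _check_resolution(resolution, spec)
    R = (spec or GridSpec()).earth_radius_km
    area = 4.0 * math.pi * R * R / (10.0 * 3 ** resolution)
    return area * 5.0 / 6.0 if pentagon else area


def centroid_spacing_km(resolution: int, spec: GridSpec | None = None) -> float:
    """Nominal centroid spacing, reference-software convention.

    Defined as the icosahedron edge arc length divided by ``3^(r/2)`` --
    i.e. the spacing of cell centers measured along an icosahedron edge,
    where the equal-area projection is most compressed.  This reproduces
    the conventional grid tables (e.g. 50.3 km at resolution 9); the mean
    planar lattice spacing is about 9% larger.
    """
    _check_resolution(resolution, spec)
    R = (spec or GridSpec()).earth_radius_km
    return _EDGE_ARC * R / 3 ** (resolution / 2.0)


def _check_resolution(resolution: int, spec: GridSpec | None = None) -> None:
    max_r = (spec or GridSpec()).max_resolution
    if not isinstance(resolution, (int, np.integer)):
        raise TypeError("resolution must be an integer")
    if resolution < 0 or resolution > max_r:
        raise ValueError(f"resolution must lie in [0, {max_r}]")


# ----------------------------------------------------------------------
# per-resolution lattice tables
# ----------------------------------------------------------------------

@dataclass
class _Lattice:
    resolution: int
    even: bool
    n: int                    # f (class I) or m (class II): edge intervals
    E: int                    # interior lattice points per icosahedron edge
    I: int                    # interior lattice points per face
    B: np.ndarray             # (2,2) lattice basis, columns u, v
    Binv: np.ndarray
    P0: np.ndarray            # planar position of corner 0
    corner_ab: np.ndarray     # (3,2) lattice coords of the triangle corners
    # interior ranking tables
    amin: int
    bmin: np.ndarray          # per a-offset
    cum: np.ndarray           # cumulative interior counts per a-offset
    a_of_rank: np.ndarray
    b_of_rank: np.ndarray

    def xy(self, a, b):
        """Planar coordinates of lattice points (face-independent)."""
        ab = np.stack([np.asarray(a, dtype=float), np.asarray(b, dtype=float)],
                      axis=-1)
        return ab @ self.B.T + self.P0

    def ab(self, xy):
        """Real-valued lattice coordinates of planar points."""
        return (np.asarray(xy) - self.P0) @ self.Binv.T


def _build_lattice(spec: GridSpec, r: int) -> _Lattice:
    proj = get_projection(spec)
    P = proj.corners_xy
    even = (r % 2 == 0)
    if even:
        n = 3 ** (r // 2)
        A = (P[1] - P[0]) / n
        Bv = (P[2] - P[0]) / n
        u, v = A, Bv
        corner_ab = np.array([(0, 0), (n, 0), (0, n)], dtype=np.int64)
        I = (n - 1) * (n - 2) // 2
    else:
        n = 3 ** ((r - 1) // 2)
        A = (P[1] - P[0]) / n
        Bv = (P[2] - P[0]) / n
        u = (2.0 * A - Bv) / 3.0
        v = (A + Bv) / 3.0
        corner_ab = np.array([(0, 0), (n, n), (-n, 2 * n)], dtype=np.int64)
        I = (3 * n * n - 3 * n + 2) // 2
    B = np.stack([u, v], axis=1)
    Binv = np.linalg.inv(B)
    E = n - 1

    # interior enumeration (row-major in a, then b)
    if even:
        amin = 1
        avals = np.arange(1, max(n - 1, 1), dtype=np.int64)
        bmin = np.ones_like(avals)
        bmax = n - 1 - avals
    else:
        amin = -(n - 1)
        avals = np.arange(amin, n, dtype=np.int64)
        bmin = np.maximum(avals + 1, 1 - 2 * avals)
        bmax = (3 * n - 1 - avals) // 2
    counts = np.maximum(bmax - bmin + 1, 0)
    cum = np.concatenate([[0], np.cumsum(counts)])
    assert cum[-1] == I, (r, cum[-1], I)
    a_of_rank = np.repeat(avals, counts)
    b_of_rank = np.concatenate(
        [np.arange(lo, lo + c, dtype=np.int64) for lo, c in zip(bmin, counts)]
    ) if I else np.empty(0, dtype=np.int64)
    return _Lattice(r, even, n, E, I, B, Binv, P[0].copy(), corner_ab,
                    amin, bmin, cum, a_of_rank, b_of_rank)


# ----------------------------------------------------------------------
# face topology: unfold maps between adjacent faces
# ----------------------------------------------------------------------

class _Topology:
    """Per-face edge bookkeeping and planar unfold maps.

    ``unfold_M[f, k]``/``unfold_t[f, k]`` map planar points of face ``f``
    lying beyond the edge opposite corner ``k`` into the plane of the
    adjacent face ``unfold_face[f, k]`` (an isometry; exact because the
    lattice construction is mirror-symmetric about every face edge).
    ``fold_M``/``fold_t`` are the inverse maps.
    """

    # edge opposite corner k, with corners ordered as the local edge
    # parameter runs: edge01 (k=2) from corner 0, edge02 (k=1) from
    # corner 0, edge12 (k=0) from corner 1
    _PAIR = ((1, 2), (0, 2), (0, 1))

    def __init__(self, spec: GridSpec):
        ico = get_icosahedron(spec)
        proj = get_projection(spec)
        P = proj.corners_xy
        nf = 20
        self.unfold_face = np.empty((nf, 3), dtype=np.int64)
        self.unfold_M = np.empty((nf, 3, 2, 2))
        self.unfold_t = np.empty((nf, 3, 2))
        self.fold_M = np.empty((nf, 3, 2, 2))
        self.fold_t = np.empty((nf, 3, 2))
        # edge tables: per face, per opposite-corner k
        self.edge_ids = np.empty((nf, 3), dtype=np.int64)
        self.edge_flip = np.zeros((nf, 3), dtype=bool)
        # owner representation for each global edge / vertex
        self.edge_owner = {}           # edge_id -> (face, k)
        self.vertex_owner = {}         # vertex id -> (face, corner index)

        for f in range(nf):
            cv = ico.corner_vertex[f]
            for k in range(3):
                i, j = self._PAIR[k]
                gi, gj = int(cv[i]), int(cv[j])
                key = (min(gi, gj), max(gi, gj))
                eid = ico.edge_id[key]
                self.edge_ids[f, k] = eid
                self.edge_flip[f, k] = gi > gj
                fa, fb = ico.edge_faces[key]
                other = fb if f == fa else fa
                self.unfold_face[f, k] = other
                if f == fa and eid not in self.edge_owner:
                    self.edge_owner[eid] = (f, k)
                # corner indices of gi, gj in the other face
                cvo = ico.corner_vertex[other]
                io = int(np.where(cvo == gi)[0][0])
                jo = int(np.where(cvo == gj)[0][0])
                M, t = _edge_isometry(P[i], P[j], P[io], P[jo], P[k], P)
                self.unfold_M[f, k] = M
                self.unfold_t[f, k] = t
                self.fold_M[f, k] = np.linalg.inv(M)
                self.fold_t[f, k] = -self.fold_M[f, k] @ t
            for ci in range(3):
                vid = int(cv[ci])
                if vid not in self.vertex_owner:
                    self.vertex_owner[vid] = (f, ci)

        # faces incident to each vertex, in cyclic order around the vertex
        self.vertex_faces = []
        for vid in range(12):
            faces = [f for f in range(nf) if vid in ico.corner_vertex[f]]
            p = ico.vertices[vid]
            north = np.array([0.0, 0.0, 1.0]) - p[2] * p
            if np.linalg.norm(north) < 1e-9:       # vertex at a pole
                north = np.array([1.0, 0.0, 0.0]) - p[0] * p
            north /= np.linalg.norm(north)
            east = np.cross(p, north)
            east = -east  # clockwise-from-north convention
            az = []
            for f in faces:
                d = ico.face_centers[f] - np.dot(ico.face_centers[f], p) * p
                az.append(math.atan2(np.dot(d, east), np.dot(d, north)))
            order = np.argsort(az)
            self.vertex_faces.append([faces[o] for o in order])


def _edge_isometry(pa_i, pa_j, pb_i, pb_j, pa_opp, corners):
    """Planar isometry taking edge (pa_i, pa_j) onto (pb_i, pb_j), chosen
    so that the half-plane beyond the edge (away from pa_opp) maps into
    the target triangle."""
    def frame(p, q):
        d = q - p
        d = d / np.linalg.norm(d)
        return d, np.array([-d[1], d[0]])

    da, na = frame(pa_i, pa_j)
    db, nb = frame(pb_i, pb_j)
    mid = 0.5 * (pa_i + pa_j)
    out = mid - pa_opp
    out = out / np.linalg.norm(out)
    for sign in (1.0, -1.0):
        Fa = np.stack([da, na], axis=1)
        Fb = np.stack([db, sign * nb], axis=1)
        M = Fb @ Fa.T
        t = pb_i - M @ pa_i
        probe = M @ (mid + 1e-3 * out) + t
        # inside target triangle? (centroid of target corners is origin)
        if np.linalg.norm(probe) < np.linalg.norm(M @ (mid - 1e-3 * out) + t):
            return M, t
    raise RuntimeError("unfold isometry selection failed")


# ----------------------------------------------------------------------
# the grid
# ----------------------------------------------------------------------

@dataclass
class CellGeometry:
    """Geometry of one cell: centroid, boundary ring, pentagon flag, area."""
    hid: int
    resolution: int
    centroid_lat_deg: float
    centroid_lon_deg: float
    boundary: np.ndarray          # (n, 2) closed ring of (lat, lon)
    is_pentagon: bool
    area_km2: float


class ISEA3HGrid:
    """The ISEA aperture-3 hexagonal grid for one :class:`GridSpec`.

    All vectorized methods accept and return numpy arrays; HIDs are
    1-based int64 per resolution.
    """

    def __init__(self, spec: GridSpec | None = None):
        self.spec = spec or GridSpec()
        self.proj = get_projection(self.spec)
        self.ico = self.proj.ico
        self.topo = _Topology(self.spec)
        self._lattices: dict[int, _Lattice] = {}

    # -- basics --------------------------------------------------------
    def cell_count(self, resolution: int) -> int:
        return cell_count(resolution, self.spec)

    def cell_area_km2(self, resolution: int, pentagon: bool = False) -> float:
        return cell_area_km2(resolution, pentagon, self.spec)

    def centroid_spacing_km(self, resolution: int) -> float:
        return centroid_spacing_km(resolution, self.spec)

    def is_pentagon(self, hids) -> np.ndarray:
        return np.asarray(hids) <= 12

    def _lat(self, r: int) -> _Lattice:
        # resolution r+1 is required internally for cell corners, hence +1
        if r < 0 or r > self.spec.max_resolution + 1:
            raise ValueError("resolution out of range")
        if r not in self._lattices:
            self._lattices[r] = _build_lattice(self.spec, r)
        return self._lattices[r]

    # -- lattice <-> HID ----------------------------------------------
    def _classify(self, face, a, b, r):
        """(face, a, b) with the point inside the closed triangle -> HID."""
        lat = self._lat(r)
        n = lat.n
        face = np.asarray(face, dtype=np.int64)
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        hid = np.zeros(a.shape, dtype=np.int64)
        cv = self.ico.corner_vertex[face]              # (N, 3)

        if lat.even:
            on = [b == 0, a == 0, a + b == n]          # edges 01, 02, 12
            t_loc = [a, b, b]
        else:
            on = [b == a, 2 * a + b == 0, a + 2 * b == 3 * n]
            t_loc = [a, -a, b - n]
        corner_hit = [on[0] & on[1], on[0] & on[2], on[1] & on[2]]

        is_vertex = corner_hit[0] | corner_hit[1] | corner_hit[2]
        vidx = np.select(corner_hit, [cv[:, 0], cv[:, 1], cv[:, 2]], default=0)
        hid[is_vertex] = vidx[is_vertex] + 1

        E, I = lat.E, lat.I
        pair_k = {0: 2, 1: 1, 2: 0}   # local pair (01,02,12) -> opposite corner
        done = is_vertex.copy()
        for p_idx in range(3):
            m = on[p_idx] & ~done
            if not m.any():
                continue
            k = pair_k[p_idx]
            eid = self.topo.edge_ids[face[m], k]
            flip = self.topo.edge_flip[face[m], k]
            t = np.asarray(t_loc[p_idx])[m]
            t = np.where(flip, n - t, t)
            hid[m] = 13 + eid * E + (t - 1)
            done |= on[p_idx]

        m = ~done
        if m.any():
            ai = a[m]
            bi = b[m]
            rank = lat.cum[ai - lat.amin] + (bi - lat.bmin[ai - lat.amin])
            hid[m] = 13 + 30 * E + face[m] * I + rank
        return hid

    def _hid_to_fab(self, hids, r):
        """HID -> owner (face, a, b) representation."""
        lat = self._lat(r)
        hids = np.asarray(hids, dtype=np.int64)
        if np.any(hids < 1) or np.any(hids > cell_count(r, self.spec)):
            raise ValueError("HID out of range for resolution")
        face = np.empty(hids.shape, dtype=np.int64)
        a = np.empty(hids.shape, dtype=np.int64)
        b = np.empty(hids.shape, dtype=np.int64)
        E, I, n = lat.E, lat.I, lat.n

        mp = hids <= 12
        if mp.any():
            vf = np.array([self.topo.vertex_owner[v][0] for v in range(12)])
            vk = np.array([self.topo.vertex_owner[v][1] for v in range(12)])
            vid = hids[mp] - 1
            face[mp] = vf[vid]
            k = vk[vid]
            a[mp] = lat.corner_ab[k, 0]
            b[mp] = lat.corner_ab[k, 1]

        me = (hids > 12) & (hids <= 12 + 30 * E)
        if me.any():
            idx = hids[me] - 13
            eid = idx // E
            t = idx % E + 1
            own = np.array([self.topo.edge_owner[e] for e in range(30)])
            f_own = own[eid, 0]
            k_own = own[eid, 1]
            flip = self.topo.edge_flip[f_own, k_own]
            t = np.where(flip, n - t, t)
            face[me] = f_own
            # opposite corner k -> local pair: k=2 -> edge 01, k=1 -> 02, k=0 -> 12
            if lat.even:
                ae = np.select([k_own == 2, k_own == 1, k_own == 0],
                               [t, np.zeros_like(t), n - t])
                be = np.select([k_own == 2, k_own == 1, k_own == 0],
                               [np.zeros_like(t), t, t])
            else:
                ae = np.select([k_own == 2, k_own == 1, k_own == 0],
                               [t, -t, n - 2 * t])
                be = np.select([k_own == 2, k_own == 1, k_own == 0],
                               [t, 2 * t, n + t])
            a[me] = ae
            b[me] = be

        mi = hids > 12 + 30 * E
        if mi.any():
            idx = hids[mi] - 13 - 30 * E
            face[mi] = idx // I
            rank = idx % I
            a[mi] = lat.a_of_rank[rank]
            b[mi] = lat.b_of_rank[rank]
        return face, a, b

    # -- canonicalization ---------------------------------------------
    def _canonicalize(self, face, a, b, r):
        """Map lattice coords possibly outside their face into a face that
        contains them (via the unfold isometries)."""
        lat = self._lat(r)
        face = np.array(face, dtype=np.int64, copy=True)
        a = np.array(a, dtype=np.int64, copy=True)
        b = np.array(b, dtype=np.int64, copy=True)
        tol = -1e-9
        for _ in range(4):
            xy = lat.xy(a, b)
            bary = self.proj.barycentric(xy[..., 0], xy[..., 1])
            k = np.argmin(bary, axis=-1)
            bad = bary[np.arange(len(k)), k] < tol
            if not bad.any():
                return face, a, b
            fb, kb = face[bad], k[bad]
            M = self.topo.unfold_M[fb, kb]
            t = self.topo.unfold_t[fb, kb]
            xy2 = np.einsum("nij,nj->ni", M, xy[bad]) + t
            face[bad] = self.topo.unfold_face[fb, kb]
            ab2 = np.rint(lat.ab(xy2)).astype(np.int64)
            a[bad] = ab2[..., 0]
            b[bad] = ab2[..., 1]
        raise RuntimeError("lattice canonicalization did not converge")

    # -- point location ------------------------------------------------
    def locate_xyz(self, xyz, resolution: int) -> np.ndarray:
        _check_resolution(resolution, self.spec)
        lat = self._lat(resolution)
        face, x, y = self.proj.forward_xyz(np.atleast_2d(xyz))
        ab = lat.ab(np.stack([x, y], axis=-1))
        qa, qb = ab[..., 0], ab[..., 1]
        # cube rounding in hex axial coordinates
        cx, cz = qa, qb
        cy = -cx - cz
        rx, ry, rz = np.rint(cx), np.rint(cy), np.rint(cz)
        dx, dy, dz = np.abs(rx - cx), np.abs(ry - cy), np.abs(rz - cz)
        fix_x = (dx >= dy) & (dx >= dz)
        fix_z = ~fix_x & (dz > dy)
        rx = np.where(fix_x, -ry - rz, rx)
        rz = np.where(fix_z, -rx - ry, rz)
        a = rx.astype(np.int64)
        b = rz.astype(np.int64)
        face, a, b = self._canonicalize(face, a, b, resolution)
        return self._classify(face, a, b, resolution)

    def locate(self, lat_deg, lon_deg, resolution: int) -> np.ndarray:
        """HID of the cell containing each point (total on the sphere)."""
        lat = np.asarray(lat_deg, dtype=float)
        lon = np.asarray(lon_deg, dtype=float)
        if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
            raise ValueError("coordinates must be finite")
        scalar = lat.ndim == 0
        out = self.locate_xyz(latlon_to_xyz(lat, lon), resolution)
        return int(out[0]) if scalar else out

    # -- centroids -----------------------------------------------------
    def centroid_xyz(self, hids, resolution: int) -> np.ndarray:
        _check_resolution(resolution, self.spec)
        lat = self._lat(resolution)
        hids = np.atleast_1d(np.asarray(hids, dtype=np.int64))
        face, a, b = self._hid_to_fab(hids, resolution)
        xy = lat.xy(a, b)
        out = self.proj.inverse_xyz(face, xy[..., 0], xy[..., 1])
        # exact vertex positions for pentagons
        mp = hids <= 12
        if mp.any():
            out[mp] = self.ico.vertices[hids[mp] - 1]
        return out

    def centroid(self, hids, resolution: int):
        """Centroid latitude/longitude (degrees) of each cell."""
        hids_arr = np.asarray(hids)
        lat, lon = xyz_to_latlon(self.centroid_xyz(hids_arr, resolution))
        if hids_arr.ndim == 0:
            return float(lat[0]), float(lon[0])
        return lat, lon

    # -- adjacency -----------------------------------------------------
    def neighbors(self, hid: int, resolution: int) -> np.ndarray:
        """HIDs of edge-adjacent cells (6 for hexagons, 5 for pentagons)."""
        _check_resolution(resolution, self.spec)
        face, a, b = self._hid_to_fab(np.array([hid]), resolution)
        cand_a = a[0] + _STEPS[:, 0]
        cand_b = b[0] + _STEPS[:, 1]
        faces = np.full(6, face[0])
        f2, a2, b2 = self._canonicalize(faces, cand_a, cand_b, resolution)
        out = self._classify(f2, a2, b2, resolution)
        uniq = list(dict.fromkeys(out.tolist()))
        if hid in uniq:
            uniq.remove(hid)
        return np.array(uniq, dtype=np.int64)

    # -- cell corners and boundaries ------------------------------------
    def _up_coords(self, a, b, r):
        """Lattice coords of the same planar point at resolution r+1."""
        if self._lat(r).even:
            return a - b, a + 2 * b
        return 2 * a + b, b - a

    def _corner_positions(self, hid: int, r: int):
        """Cell corner planar positions [(face, xy), ...] in ring order."""
        up = self._lat(r + 1)
        if hid <= 12:
            vid = hid - 1
            reps: list[list] = []
            positions: list[np.ndarray] = []
            for f in self.topo.vertex_faces[vid]:
                ci = int(np.where(self.ico.corner_vertex[f] == vid)[0][0])
                ca, cb = up.corner_ab[ci]
                for s in _STEPS:
                    aa, bb = ca + s[0], cb + s[1]
                    xy = up.xy(aa, bb)
                    bary = self.proj.barycentric(xy[0], xy[1])[0]
                    if bary.min() >= -1e-9:
                        p = self.proj.inverse_xyz(np.array([f]),
                                                  xy[0:1], xy[1:2])[0]
                        for gi, q in enumerate(positions):
                            if np.linalg.norm(p - q) < 1e-6:
                                reps[gi].append((f, xy, p))
                                break
                        else:
                            positions.append(p)
                            reps.append([(f, xy, p)])
            center = self.ico.vertices[vid]
        else:
            face, a, b = self._hid_to_fab(np.array([hid]), r)
            face = int(face[0])
            ua, ub = self._up_coords(int(a[0]), int(b[0]), r)
            reps = []
            for s in _STEPS:
                xy = up.xy(ua + s[0], ub + s[1])
                reps.append([(face, xy, None)])
            lat0 = self._lat(r)
            cxy = lat0.xy(int(a[0]), int(b[0]))
            center = self.proj.inverse_xyz(np.array([face]),
                                           cxy[0:1], cxy[1:2])[0]
        return reps, center

    def _project_boundary_points(self, face: int, pts: np.ndarray) -> np.ndarray:
        """Inverse-project planar points of face ``face``, unfolding the
        ones that lie beyond a face edge into the adjacent face."""
        faces = np.full(len(pts), face, dtype=np.int64)
        pts = np.array(pts, dtype=float, copy=True)
        for _ in range(2):
            bary = self.proj.barycentric(pts[:, 0], pts[:, 1])
            k = np.argmin(bary, axis=-1)
            bad = bary[np.arange(len(k)), k] < -1e-12
            if not bad.any():
                break
            fb, kb = faces[bad], k[bad]
            M = self.topo.unfold_M[fb, kb]
            t = self.topo.unfold_t[fb, kb]
            pts[bad] = np.einsum("nij,nj->ni", M, pts[bad]) + t
            faces[bad] = self.topo.unfold_face[fb, kb]
        return self.proj.inverse_xyz(faces, pts[:, 0], pts[:, 1])

    def cell_boundary_xyz(self, hid: int, resolution: int,
                          densify_per_edge: int = 50) -> np.ndarray:
        """Closed boundary ring of a cell as unit vectors.

        Corners are exact (they are resolution ``r+1`` cell centers);
        edges are straight in the unfolded face plane and densified with
        ``densify_per_edge`` interior points before inverse projection.
        """
        _check_resolution(resolution, self.spec)
        if densify_per_edge < 0:
            raise ValueError("densify_per_edge must be >= 0")
        reps, center = self._corner_positions(hid, resolution)
        # order corners around the center (clockwise-from-north azimuth)
        pos = []
        for rep in reps:
            f, xy, p = rep[0]
            if p is None:
                p = self._project_boundary_points(f, xy[None, :])[0]
                rep[0] = (f, xy, p)
            pos.append(p)
        pos = np.asarray(pos)
        north = np.array([0.0, 0.0, 1.0]) - center[2] * center
        if np.linalg.norm(north) < 1e-9:
            north = np.array([1.0, 0.0, 0.0]) - center[0] * center
        north /= np.linalg.norm(north)
        east = np.cross(north, center)
        d = pos - (pos @ center)[:, None] * center
        az = np.arctan2(d @ east, d @ north)
        order = np.argsort(az)
        reps = [reps[i] for i in order]

        ring = []
        nc = len(reps)
        for i in range(nc):
            c1, c2 = reps[i], reps[(i + 1) % nc]
            f1s = {f for f, _, _ in c1}
            seg = None
            for f, xy, _ in c2:
                if f in f1s:
                    xy1 = next(x for ff, x, _ in c1 if ff == f)
                    seg = (f, xy1, xy)
                    break
            if seg is None:
                # corners in adjacent faces: fold c2's face onto c1's
                f1, xy1, _ = c1[0]
                f2, xy2, _ = c2[0]
                k1 = int(np.where(self.topo.unfold_face[f1] == f2)[0][0])
                xy2_in_f1 = self.topo.fold_M[f1, k1] @ xy2 \
                    + self.topo.fold_t[f1, k1]
                seg = (f1, xy1, xy2_in_f1)
            f, p1, p2 = seg
            ts = np.linspace(0.0, 1.0, densify_per_edge + 2)[:-1]
            pts = p1[None, :] * (1 - ts[:, None]) + p2[None, :] * ts[:, None]
            ring.append(self._project_boundary_points(f, pts))
        ring.append(ring[0][:1])
        return np.concatenate(ring, axis=0)

    def cell_geometry(self, hid: int, resolution: int,
                      densify_per_edge: int = 50) -> CellGeometry:
        """Full geometry of one cell (centroid, ring, pentagon flag, area)."""
        hid = int(hid)
        if hid < 1 or hid > cell_count(resolution, self.spec):
            raise ValueError("HID out of range for resolution")
        ring_xyz = self.cell_boundary_xyz(hid, resolution, densify_per_edge)
        lat, lon = xyz_to_latlon(ring_xyz)
        # unwrap longitudes to be contiguous with the centroid's
        clat, clon = self.centroid(hid, resolution)
        lon = clon + (lon - clon + 180.0) % 360.0 - 180.0
        pent = hid <= 12
        return CellGeometry(
            hid=hid, resolution=resolution,
            centroid_lat_deg=clat, centroid_lon_deg=clon,
            boundary=np.stack([lat, lon], axis=1),
            is_pentagon=pent,
            area_km2=cell_area_km2(resolution, pent, self.spec),
        )
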