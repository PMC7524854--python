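"""Triangle meshes: construction, area sampling, ray casting, watertightness.

Minimal by design — only the operations the simulator and ICP need. Faces are
oriented counter-clockwise when viewed from outside, so face normals of a
closed mesh point outward and signed volume is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError
from .transforms import RigidTransform


@dataclass(frozen=True)
class TriangleMesh:
    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) int indices

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or not np.all(np.isfinite(v)):
            raise InvalidGeometryError("vertices must be a finite (V, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise InvalidGeometryError("faces must be (F, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise InvalidGeometryError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- basic quantities ---------------------------------------------------

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalized:
            lens = np.linalg.norm(n, axis=1, keepdims=True)
            lens[lens == 0] = 1.0
            n = n / lens
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    @property
    def volume(self) -> float:
        """Signed volume by the divergence theorem (positive for outward CCW)."""
        tri = self.triangles()
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    @property
    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two consistently wound faces."""
        if self.n_faces == 0:
            return False
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        und = np.sort(directed, axis=1)
        _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        if not np.all(counts == 2):
            return False
        # consistent orientation: each undirected edge appears once per direction
        key = directed[:, 0] * (len(self.vertices) + 1) + directed[:, 1]
        return len(np.unique(key)) == len(key)

    def transformed(self, T: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(T.apply(self.vertices), self.faces)

    # -- sampling -----------------------------------------------------------

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` points sampled uniformly by area; also see sample_surface_with_faces."""
        return self.sample_surface_with_faces(n, rng)[0]

    def sample_surface_with_faces(self, n: int, rng: np.random.Generator):
        if n < 1:
            raise InvalidGeometryError("sample count must be >= 1")
        areas = self.face_areas()
        total = areas.sum()
        if total <= 0:
            raise InvalidGeometryError("mesh has zero surface area")
        fi = rng.choice(self.n_faces, size=n, p=areas / total)
        tri = self.vertices[self.faces[fi]]
        # uniform barycentric via the square-root trick
        r1 = np.sqrt(rng.random(n))
        r2 = rng.random(n)
        pts = (
            (1 - r1)[:, None] * tri[:, 0]
            + (r1 * (1 - r2))[:, None] * tri[:, 1]
            + (r1 * r2)[:, None] * tri[:, 2]
        )
        return pts, fi

    # -- vertex curvature proxy --------------------------------------------

    def angle_deficit(self) -> np.ndarray:
        """Per-vertex 2π minus the sum of incident triangle angles.

        A discrete Gaussian-curvature proxy; large values mark ridge/notch
        features, which is where the simulator drops its landmarks.
        """
        tri = self.triangles()
        deficit = np.full(len(self.vertices), 2.0 * np.pi)
        for corner in range(3):
            a = tri[:, corner]
            b = tri[:, (corner + 1) % 3]
            c = tri[:, (corner + 2) % 3]
            u, v = b - a, c - a
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.subtract.at(deficit, self.faces[:, corner], ang)
        return deficit

    # -- ray casting --------------------------------------------------------

    def ray_first_hit(self, origins: np.ndarray, directions: np.ndarray, eps: float = 1e-9):
        """Möller–Trumbore nearest intersection per ray.

        Returns (t, face_index); t = +inf and face_index = -1 for misses.
        Directions need not be unit length; t is in direction-vector units.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        n_rays = origins.shape[0]
        t_best = np.full(n_rays, np.inf)
        f_best = np.full(n_rays, -1, dtype=np.int64)
        tri = self.triangles()
        e1 = tri[:, 1] - tri[:, 0]  # (F,3)
        e2 = tri[:, 2] - tri[:, 0]
        v0 = tri[:, 0]
        chunk = max(1, int(4e6 // max(1, self.n_faces)))
        for s in range(0, n_rays, chunk):
            o = origins[s : s + chunk][:, None, :]  # (R,1,3)
            d = directions[s : s + chunk][:, None, :]
            pvec = np.cross(d, e2[None, :, :])  # (R,F,3)
            det = np.einsum("rfk,fk->rf", pvec, e1)
            ok = np.abs(det) > eps
            inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
            tvec = o - v0[None, :, :]
            u = np.einsum("rfk,rfk->rf", tvec, pvec) * inv_det
            qvec = np.cross(tvec, e1[None, :, :])
            v = np.einsum("rfk,rfk->rf", qvec, d) * inv_det
            t = np.einsum("rfk,fk->rf", qvec, e2) * inv_det
            hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
            t = np.where(hit, t, np.inf)
            idx = np.argmin(t, axis=1)
            rows = np.arange(t.shape[0])
            tmin = t[rows, idx]
            t_best[s : s + chunk] = tmin
            f_best[s : s + chunk] = np.where(np.isfinite(tmin), idx, -1)
        return t_best, f_best

    # -- distances ----------------------------------------------------------

    def distance_to_points(self, points: np.ndarray) -> np.ndarray:
        """Exact unsigned distance from each query point to the mesh surface."""
        return self.closest_points(points)[1]

    def closest_points(self, points: np.ndarray):
        """Exact closest surface point per query (brute force over all faces).

        Returns (closest (P, 3), distance (P,), face_index (P,)). O(P·F);
        fine for oracles and one-off checks — registration uses the
        sample-accelerated variant in the icp module.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tri = self.triangles()
        n = points.shape[0]
        out_c = np.empty((n, 3))
        out_d = np.empty(n)
        out_f = np.empty(n, dtype=np.int64)
        chunk = max(1, int(2e6 // max(1, self.n_faces)))
        for s in range(0, n, chunk):
            p = points[s : s + chunk]
            closest, d2 = point_triangle_closest(p[:, None, :], tri[None, :, :, :])
            idx = np.argmin(d2, axis=1)
            rows = np.arange(p.shape[0])
            out_c[s : s + chunk] = closest[rows, idx]
            out_d[s : s + chunk] = np.sqrt(d2[rows, idx])
            out_f[s : s + chunk] = idx
        return out_c, out_d, out_f


def point_triangle_closest(points: np.ndarray, tri: np.ndarray):
    """Closest point on each triangle to each query point (broadcasting).

    ``points``: (..., 3); ``tri``: (..., 3, 3) with broadcast-compatible
    leading dims. Returns (closest (..., 3), squared distance (...)).
    Ericson's real-time collision detection region test, vectorised.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)
    bp = points - b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)
    cp = points - c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom

    # interior projection
    closest = a + v[..., None] * ab + w[..., None] * ac

    # edge regions (checked before vertices so vertex masks win on overlap)
    on_ab = (d1 * d4 - d3 * d2 <= 0) & (d1 >= 0) & (d3 <= 0)
    tpar = d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3)
    closest = np.where(on_ab[..., None], a + tpar[..., None] * ab, closest)
    on_ac = (d5 * d2 - d1 * d6 <= 0) & (d2 >= 0) & (d6 <= 0)
    tpar = d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6)
    closest = np.where(on_ac[..., None], a + tpar[..., None] * ac, closest)
    on_bc = (d3 * d6 - d5 * d4 <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    tpar = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1.0, (d4 - d3) + (d5 - d6))
    closest = np.where(on_bc[..., None], b + tpar[..., None] * (c - b), closest)

    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[..., None], np.broadcast_to(a, closest.shape), closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[..., None], np.broadcast_to(b, closest.shape), closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[..., None], np.broadcast_to(c, closest.shape), closest)

    diff = points - closest
    return closest, np.einsum("...k,...k->...", diff, diff)


# -- primitive constructors -------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def icosphere(subdivisions: int = 3) -> TriangleMesh:
    """Unit sphere from a subdivided icosahedron (20 * 4**s faces)."""
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = verts_list[i] + verts_list[j]
                verts_list.append(m / np.linalg.norm(m))
                edge_mid[key] = len(verts_list) - 1
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=np.int64)
    return TriangleMesh(verts, faces)


def make_sheet(
    center, size_x: float, size_y: float, n_x: int = 20, n_y: int = 20, sag_mm: float = 0.0
) -> TriangleMesh:
    """Open rectangular sheet in the x-y plane at ``center`` (z up).

    ``sag_mm`` adds a gentle downward parabolic sag toward the centre so the
    sheet is not perfectly planar; normals point in -z (down, toward a liver
    below), matching a diaphragm seen from underneath.
    """
    cx, cy, cz = (float(v) for v in np.asarray(center, dtype=float))
    xs = np.linspace(-size_x / 2, size_x / 2, n_x + 1)
    ys = np.linspace(-size_y / 2, size_y / 2, n_y + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    # max-norm radius: 0 at the centre, 1 on the whole rectangular rim
    r2 = np.maximum(np.abs(gx) / (size_x / 2), np.abs(gy) / (size_y / 2)) ** 2
    gz = cz + sag_mm * (r2 - 1.0)  # sag_mm below cz at the centre, cz at the rim
    verts = np.column_stack([gx.ravel() + cx, gy.ravel() + cy, gz.ravel()])
    faces = []
    for i in range(n_x):
        for j in range(n_y):
            v00 = i * (n_y + 1) + j
            v01 = v00 + 1
            v10 = v00 + (n_y + 1)
            v11 = v10 + 1
            # wound so normals face -z
            faces += [[v00, v01, v10], [v01, v11, v10]]
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))
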