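"""Low-level mesh geometry kernels.

Exact nearest point on a triangulated surface, ray/mesh intersection and
rigid least-squares (Kabsch) alignment.  These kernels back the deviation
analysis, footprint tracing and breakthrough-point construction, so they are
implemented here with explicit guarantees rather than delegated:

* nearest-point queries prune candidate triangles with a k-d tree on triangle
  centroids and then evaluate exact point-triangle distances; a radius
  fallback makes the result exact, not approximate, regardless of triangle
  size variation;
* ray casting is plain vectorised Moller-Trumbore over all triangles, which
  is ample for the footprint submeshes it is used on.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, EmptyInputError

__all__ = [
    "NearestSurface",
    "closest_point_on_mesh",
    "ray_mesh_intersections",
    "sample_surface",
    "kabsch",
    "rotation_about_axis",
]


class NearestSurface:
    """Exact nearest-point queries against a fixed triangulated surface.

    Parameters
    ----------
    mesh:
        Target surface.  Triangles are indexed once; repeated queries reuse
        the tree.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise EmptyInputError("cannot build a nearest-surface index on an empty mesh")
        self.mesh = mesh
        triangles = mesh.triangles.view(np.ndarray)
        self._face_map = np.arange(len(triangles))
        # oversized triangles make the exactness fallback radius huge; split
        # them (a subdivision of the same surface, distances are unchanged)
        edge_len = np.linalg.norm(
            np.roll(triangles, -1, axis=1) - triangles, axis=2
        )
        target = 4.0 * np.median(edge_len)
        if edge_len.max() > 2.0 * target:
            verts, faces, index = trimesh.remesh.subdivide_to_size(
                mesh.vertices.view(np.ndarray),
                mesh.faces.view(np.ndarray),
                max_edge=target,
                return_index=True,
            )
            triangles = verts[faces]
            self._face_map = np.asarray(index)
        self._triangles = triangles
        self._centroids = self._triangles.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        # max distance from a triangle centroid to its own vertices: bounds
        # how far a true nearest triangle's centroid can be from the k-NN front
        self._reach = float(
            np.linalg.norm(self._triangles - self._centroids[:, None, :], axis=2).max()
        )

    def query(self, points: np.ndarray, k: int = 16):
        """Return ``(closest_points, distances, face_indices)`` for ``points``.

        Exact: if the k-nearest-centroid candidate set cannot be proven to
        contain the true nearest triangle, the query falls back to a ball
        search with a guaranteed radius.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n_faces = len(self._triangles)
        k = min(k, n_faces)
        d_cent, idx = self._tree.query(points, k=k)
        if k == 1:
            d_cent = d_cent[:, None]
            idx = idx[:, None]

        closest, dist, face = self._evaluate_candidates(points, idx)

        # guarantee: any face outside the candidate set has centroid distance
        # >= d_cent[:, -1], hence surface distance >= d_cent[:, -1] - reach
        if k < n_faces:
            unsafe = dist > d_cent[:, -1] - self._reach
            if np.any(unsafe):
                for i in np.nonzero(unsafe)[0]:
                    radius = dist[i] + self._reach + 1e-12
                    cand = np.asarray(self._tree.query_ball_point(points[i], radius))
                    c, d, f = self._evaluate_candidates(points[i : i + 1], cand[None, :])
                    closest[i], dist[i], face[i] = c[0], d[0], f[0]
        return closest, dist, self._face_map[face]

    def _evaluate_candidates(self, points, idx):
        n, k = idx.shape
        flat_idx = idx.reshape(-1)
        tris = self._triangles[flat_idx]
        pts = np.repeat(points, k, axis=0)
        cp = trimesh.triangles.closest_point(tris, pts).reshape(n, k, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        best = d.argmin(axis=1)
        rows = np.arange(n)
        return cp[rows, best], d[rows, best], idx[rows, best]


def closest_point_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray):
    """One-shot exact nearest point on ``mesh`` for each query point."""
    return NearestSurface(mesh).query(points)


def ray_mesh_intersections(mesh: trimesh.Trimesh, origin, direction, eps: float = 1e-12):
    """Intersect a single ray (both signs of ``t`` are reported) with a mesh.

    Moller-Trumbore over every triangle.  Returns ``(locations, t, face_idx)``
    sorted by ``|t|``; ``locations = origin + t * direction``.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise DegenerateGeometryError("ray direction must be non-zero")
    direction = direction / nrm

    tri = mesh.triangles.view(np.ndarray)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.zeros_like(det)
    inv_det[ok] = 1.0 / det[ok]
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", direction[None, :].repeat(len(tri), 0), qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    idx = np.nonzero(hit)[0]
    t = t[idx]
    order = np.argsort(np.abs(t))
    t = t[order]
    idx = idx[order]
    locations = origin[None, :] + t[:, None] * direction[None, :]
    return locations, t, idx


def sample_surface(mesh: trimesh.Trimesh, count: int, rng: np.random.Generator):
    """Area-uniform random points on a surface (deterministic per ``rng``)."""
    areas = mesh.area_faces
    total = areas.sum()
    if total <= 0:
        raise EmptyInputError("mesh has zero surface area")
    face_idx = rng.choice(len(areas), size=count, p=areas / total)
    r1 = rng.random(count)
    r2 = rng.random(count)
    # uniform barycentric via square-root trick
    s = np.sqrt(r1)
    b0 = 1.0 - s
    b1 = s * (1.0 - r2)
    b2 = s * r2
    tri = mesh.triangles.view(np.ndarray)[face_idx]
    pts = b0[:, None] * tri[:, 0] + b1[:, None] * tri[:, 1] + b2[:, None] * tri[:, 2]
    return pts, face_idx


def kabsch(src: np.ndarray, dst: np.ndarray, weights=None):
    """Least-squares rigid transform (R, t) with ``R @ src + t ~= dst``.

    Weighted Kabsch/Umeyama without scaling.  Raises on degenerate (rank < 2)
    configurations such as collinear point sets.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 paired points for a rigid fit")
    if weights is None:
        weights = np.ones(len(src))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu_s = (w[:, None] * src).sum(axis=0)
    mu_d = (w[:, None] * dst).sum(axis=0)
    s = src - mu_s
    d = dst - mu_d
    H = (w[:, None] * s).T @ d
    # rank-deficient H => points (nearly) collinear, rotation underdetermined
    sv = np.linalg.svd(H, compute_uv=False)
    scale = max(sv[0], 1e-300)
    if sv[1] / scale < 1e-9:
        raise DegenerateGeometryError("point configuration is collinear; rigid fit is degenerate")
    U, _, Vt = np.linalg.svd(H)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return R, t


def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
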