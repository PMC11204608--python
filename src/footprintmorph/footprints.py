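"""Footprint analysis: tracing paint contact areas onto the bone surface and
deriving area, centroid, best-fit plane, breakthrough point and subdivisions.

The *footprint* of a muscle attachment is the set of bone-surface faces that
lie directly under the radiopaque paint mark.  Tracing is automated: a bone
face belongs to the footprint when its centroid is within ``epsilon`` of the
paint surface *and* the displacement to the nearest paint point lies within
a cone around the face normal.  The normal-cone test expresses "paint
overlying the face": without it, faces laterally adjacent to the paint rim
(within epsilon of the paint's edge, but not under it) would be swept in and
the footprint systematically dilated by ~sqrt(epsilon^2 - shell^2) beyond
the painted boundary.

The *breakthrough point* — the single-point attachment proxy used by
musculoskeletal models — is where the line through the footprint centroid
along the best-fit-plane normal pierces the footprint surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import (
    DegenerateGeometryError,
    EmptyFootprintError,
    EmptyInputError,
    ParameterError,
    SubdivisionError,
)
from .geometry import NearestSurface, ray_mesh_intersections

__all__ = [
    "Footprint",
    "SubdivisionSpec",
    "trace_contact_area",
    "assign_footprints",
    "footprint_centroid",
    "best_fit_plane",
    "breakthrough_point",
    "subdivide",
]

DEFAULT_TRACE_EPSILON = 0.5
DEFAULT_MAX_NORMAL_ANGLE_DEG = 45.0


@dataclass
class Footprint:
    """A traced attachment footprint: a submesh of bone faces plus derived
    quantities.  ``area`` is exactly the sum of submesh face areas; the
    best-fit plane and breakthrough point are computed on first access and
    cached."""

    submesh: trimesh.Trimesh
    attachment_name: str = "attachment"
    attachment_role: str = "origin"
    face_indices: np.ndarray | None = None  # indices into the parent bone mesh
    _plane: tuple | None = field(default=None, repr=False)
    _breakthrough: np.ndarray | None = field(default=None, repr=False)
    _fallback: bool = field(default=False, repr=False)

    def __post_init__(self):
        if len(self.submesh.faces) == 0:
            raise EmptyFootprintError("footprint submesh has no faces")
        if self.attachment_role not in ("origin", "insertion"):
            raise ParameterError("attachment_role must be 'origin' or 'insertion'")
        if self.face_indices is None:
            self.face_indices = np.arange(len(self.submesh.faces))
        else:
            self.face_indices = np.asarray(self.face_indices, dtype=int)

    @classmethod
    def from_faces(
        cls,
        bone_mesh: trimesh.Trimesh,
        face_indices: np.ndarray,
        attachment_name: str = "attachment",
        attachment_role: str = "origin",
    ) -> "Footprint":
        face_indices = np.asarray(face_indices, dtype=int)
        if face_indices.size == 0:
            raise EmptyFootprintError(f"no faces selected for {attachment_name!r}")
        sub = bone_mesh.submesh([face_indices], append=True)
        return cls(sub, attachment_name, attachment_role, face_indices=face_indices)

    @property
    def area(self) -> float:
        """Footprint area in mm^2 (exact sum of submesh face areas)."""
        return float(self.submesh.area_faces.sum())

    @property
    def centroid(self) -> np.ndarray:
        return footprint_centroid(self)

    @property
    def plane(self) -> tuple[np.ndarray, np.ndarray]:
        if self._plane is None:
            self._plane = best_fit_plane(self)
        return self._plane

    @property
    def breakthrough_point(self) -> np.ndarray:
        if self._breakthrough is None:
            self._breakthrough, self._fallback = _breakthrough(self)
        return self._breakthrough

    @property
    def breakthrough_fallback(self) -> bool:
        _ = self.breakthrough_point
        return self._fallback


def trace_contact_area(
    bone: trimesh.Trimesh,
    paint: trimesh.Trimesh,
    epsilon: float = DEFAULT_TRACE_EPSILON,
    max_normal_angle_deg: float = DEFAULT_MAX_NORMAL_ANGLE_DEG,
    min_component_frac: float = 0.05,
    attachment_name: str = "attachment",
    attachment_role: str = "origin",
) -> Footprint:
    """Trace the contact area of a paint surface onto the bone surface.

    Selects bone faces whose centroid lies within ``epsilon`` of the paint
    surface with the paint directly overlying the face (displacement within
    ``max_normal_angle_deg`` of the face normal).  Connected components
    smaller than ``min_component_frac`` of the largest (by area) are
    dropped as spurious contacts.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    if len(bone.faces) == 0 or len(paint.faces) == 0:
        raise EmptyInputError("bone and paint meshes must be non-empty")
    selected = _candidate_faces(bone, NearestSurface(paint), epsilon, max_normal_angle_deg)
    if not selected.any():
        raise EmptyFootprintError(
            f"no bone face lies within {epsilon} mm under the paint surface"
        )
    keep = _prune_components(bone, selected, min_component_frac)
    return Footprint.from_faces(bone, np.nonzero(keep)[0], attachment_name, attachment_role)


_CONTACT_TOL = 0.25  # mm: distances below this count as direct paint contact


def _boundary_edge_segments(mesh: trimesh.Trimesh) -> np.ndarray:
    """(n, 2, 3) endpoints of the mesh's open-boundary edges."""
    edges, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
    boundary = edges[counts == 1]
    return mesh.vertices.view(np.ndarray)[boundary]


def _on_segments(points: np.ndarray, segments: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Whether each point lies within ``tol`` of any of the segments."""
    if len(segments) == 0:
        return np.zeros(len(points), dtype=bool)
    a = segments[:, 0]
    ab = segments[:, 1] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        ap = p - a
        t = np.clip(np.einsum("ij,ij->i", ap, ab) / denom, 0.0, 1.0)
        d2 = ((ap - t[:, None] * ab) ** 2).sum(axis=1)
        out[i] = d2.min() <= tol * tol
    return out


def _candidate_faces(
    bone: trimesh.Trimesh,
    paint_index: NearestSurface,
    epsilon: float,
    max_normal_angle_deg: float,
) -> np.ndarray:
    """Faces directly overlain by the paint surface.

    Three-part test on each bone face centroid: (1) within ``epsilon`` of
    the paint surface; (2) the nearest paint point is not on the paint's
    open rim (a point whose closest paint lies on the rim edge sits *beside*
    the mark, not under it); (3) the paint is either in direct contact
    (distance below a contact tolerance) or overhead, i.e. the displacement
    lies within ``max_normal_angle_deg`` of the face normal.
    """
    centers = bone.triangles_center
    out = np.zeros(len(centers), dtype=bool)
    # cheap AABB prefilter: nothing outside the inflated paint bounds can match
    lo = paint_index.mesh.bounds[0] - epsilon
    hi = paint_index.mesh.bounds[1] + epsilon
    box = np.all((centers >= lo) & (centers <= hi), axis=1)
    if not box.any():
        return out
    idx = np.nonzero(box)[0]
    closest, dist, _ = paint_index.query(centers[idx])
    near = dist <= epsilon
    if not near.any():
        return out
    idx, closest, dist = idx[near], closest[near], dist[near]
    v = closest - centers[idx]
    normals = bone.face_normals[idx]
    cos_ang = np.ones(len(v))
    moving = dist > 1e-9
    cos_ang[moving] = np.einsum("ij,ij->i", v[moving], normals[moving]) / dist[moving]
    ok = (dist <= _CONTACT_TOL) | (cos_ang >= math.cos(math.radians(max_normal_angle_deg)))
    rim = _boundary_edge_segments(paint_index.mesh)
    if len(rim) > 0 and ok.any():
        on_rim = _on_segments(closest[ok], rim)
        keep = np.nonzero(ok)[0][~on_rim]
    else:
        keep = np.nonzero(ok)[0]
    out[idx[keep]] = True
    return out


def _prune_components(bone: trimesh.Trimesh, selected: np.ndarray, frac: float) -> np.ndarray:
    sel_idx = np.nonzero(selected)[0]
    pos = -np.ones(len(selected), dtype=int)
    pos[sel_idx] = np.arange(len(sel_idx))
    adj = bone.face_adjacency
    both = selected[adj[:, 0]] & selected[adj[:, 1]]
    edges = pos[adj[both]]
    components = trimesh.graph.connected_components(edges, nodes=np.arange(len(sel_idx)))
    areas = bone.area_faces
    comp_areas = [areas[sel_idx[c]].sum() for c in components]
    largest = max(comp_areas)
    keep = np.zeros_like(selected)
    for comp, a in zip(components, comp_areas):
        if a >= frac * largest:
            keep[sel_idx[comp]] = True
    return keep


def assign_footprints(
    bone: trimesh.Trimesh,
    paints: dict[str, trimesh.Trimesh],
    epsilon: float = DEFAULT_TRACE_EPSILON,
    max_normal_angle_deg: float = DEFAULT_MAX_NORMAL_ANGLE_DEG,
    min_component_frac: float = 0.05,
    roles: dict[str, str] | None = None,
) -> dict[str, Footprint]:
    """Trace several (possibly overlapping) paint marks on one bone.

    Faces claimed by more than one mark go to the nearer paint surface;
    exact ties break to the lexicographically first attachment name, so
    the assignment is deterministic.
    """
    roles = roles or {}
    names = sorted(paints)
    dists = np.full((len(names), len(bone.faces)), np.inf)
    masks = np.zeros((len(names), len(bone.faces)), dtype=bool)
    for i, name in enumerate(names):
        index = NearestSurface(paints[name])
        masks[i] = _candidate_faces(bone, index, epsilon, max_normal_angle_deg)
        if masks[i].any():
            centers = bone.triangles_center[masks[i]]
            _, d, _ = index.query(centers)
            dists[i, masks[i]] = d
    # nearest paint wins; ties go to the first (lexicographically) name
    winner = np.argmin(dists, axis=0)
    out = {}
    for i, name in enumerate(names):
        mine = masks[i] & (winner == i)
        if not mine.any():
            raise EmptyFootprintError(f"attachment {name!r} claimed no bone face")
        keep = _prune_components(bone, mine, min_component_frac)
        out[name] = Footprint.from_faces(
            bone, np.nonzero(keep)[0], name, roles.get(name, "origin")
        )
    return out


def footprint_centroid(fp: Footprint) -> np.ndarray:
    """Area-weighted mean of the footprint's face centroids."""
    areas = fp.submesh.area_faces
    total = areas.sum()
    if total <= 0:
        raise EmptyInputError("footprint has zero total area")
    return np.asarray(
        (areas[:, None] * fp.submesh.triangles_center).sum(axis=0) / total, dtype=float
    )


def best_fit_plane(fp: Footprint) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted orthogonal-regression plane through the centroid.

    The normal is the eigenvector of the smallest eigenvalue of the
    area-weighted covariance of face centroids, with its sign chosen
    outward from the bone (aligned with the mean face normal).
    """
    centers = fp.submesh.triangles_center
    areas = fp.submesh.area_faces
    centroid = footprint_centroid(fp)
    d = centers - centroid
    cov = (areas[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / areas.sum()
    evals, evecs = np.linalg.eigh(cov)
    # collinear face centroids: two vanishing eigenvalues
    scale = max(evals[2], 1e-300)
    if evals[1] / scale < 1e-10:
        raise DegenerateGeometryError("face centroids are collinear; plane is degenerate")
    normal = evecs[:, 0]
    outward = (areas[:, None] * fp.submesh.face_normals).sum(axis=0)
    if normal @ outward < 0:
        normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def _breakthrough(fp: Footprint) -> tuple[np.ndarray, bool]:
    centroid, normal = fp.plane
    surface = NearestSurface(fp.submesh)
    nearest, dist, _ = surface.query(centroid[None, :])
    if dist[0] <= 1e-9:
        # centroid already on the (planar) footprint surface
        return nearest[0], False
    locations, t, _ = ray_mesh_intersections(fp.submesh, centroid, normal)
    if len(locations) > 0:
        return locations[0], False
    # no intersection (e.g. annular footprint): nearest surface point
    return nearest[0], True


def breakthrough_point(fp: Footprint) -> np.ndarray:
    """Intersection of the centroid's plane-normal line with the footprint
    surface (nearest intersection to the centroid); falls back to the
    nearest surface point when the line misses the footprint entirely
    (``fp.breakthrough_fallback`` is then set)."""
    return fp.breakthrough_point


# --------------------------------------------------------------------------
# subdivision

_RULES = ("linear_thirds", "plane_split", "vastus_intermedius_2x3", "thinnest_part")


@dataclass
class SubdivisionSpec:
    """Parameters of a footprint subdivision rule.

    * ``linear_thirds``: three equal-length parts along the proximal-distal
      chord (``axis_endpoints`` or extremes along ``axis_hint``).
    * ``plane_split``: two parts by the plane through ``plane_points``.
    * ``vastus_intermedius_2x3``: a halving plane through the most proximal
      point, most distal point and ``mid_point`` (default: midpoint of the
      medial/lateral extremes), crossed with length-wise thirds (6 parts).
    * ``thinnest_part``: two parts cut where the footprint is narrowest.
    """

    rule: str
    axis_endpoints: np.ndarray | None = None  # (2, 3) proximal, distal
    plane_points: np.ndarray | None = None  # (3, 3)
    mid_point: np.ndarray | None = None
    axis_hint: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self):
        if self.rule not in _RULES:
            raise ParameterError(f"unknown subdivision rule {self.rule!r}; use one of {_RULES}")
        if self.rule == "plane_split" and self.plane_points is None:
            raise ParameterError("plane_split requires plane_points (3 points)")
        if self.plane_points is not None:
            self.plane_points = np.asarray(self.plane_points, dtype=float).reshape(3, 3)
        if self.axis_endpoints is not None:
            self.axis_endpoints = np.asarray(self.axis_endpoints, dtype=float).reshape(2, 3)
        self.axis_hint = np.asarray(self.axis_hint, dtype=float).reshape(3)


def _chord(fp: Footprint, spec: SubdivisionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Proximal and distal extreme points of the footprint."""
    if spec.axis_endpoints is not None:
        return spec.axis_endpoints[0], spec.axis_endpoints[1]
    verts = fp.submesh.vertices
    proj = verts @ spec.axis_hint
    return verts[proj.argmax()], verts[proj.argmin()]  # proximal (max y), distal


def _split_by_labels(fp: Footprint, labels: np.ndarray, n_parts: int) -> list[Footprint]:
    children = []
    for part in range(n_parts):
        mask = labels == part
        if not mask.any():
            raise SubdivisionError(
                f"subdivision of {fp.attachment_name!r} produced an empty part ({part})"
            )
        sub = fp.submesh.submesh([np.nonzero(mask)[0]], append=True)
        child = Footprint(
            sub,
            attachment_name=f"{fp.attachment_name}_part{part + 1}",
            attachment_role=fp.attachment_role,
            face_indices=fp.face_indices[mask],
        )
        children.append(child)
    return children


def _plane_normal(points: np.ndarray) -> np.ndarray:
    n = np.cross(points[1] - points[0], points[2] - points[0])
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateGeometryError("subdivision plane points are collinear")
    return n / nn


def subdivide(fp: Footprint, spec: SubdivisionSpec) -> list[Footprint]:
    """Split a footprint into parts for per-part breakthrough points.

    Faces are assigned whole (by face centroid side, never split), so the
    children partition the parent's face set and areas are conserved
    exactly.  Every child recomputes its own centroid, plane and
    breakthrough point.
    """
    centers = fp.submesh.triangles_center

    if spec.rule == "linear_thirds":
        proximal, distal = _chord(fp, spec)
        axis = distal - proximal
        L = np.linalg.norm(axis)
        if L < 1e-9:
            raise DegenerateGeometryError("degenerate proximal-distal chord")
        t = (centers - proximal) @ (axis / L) / L
        labels = np.clip(np.floor(t * 3).astype(int), 0, 2)
        return _split_by_labels(fp, labels, 3)

    if spec.rule == "plane_split":
        normal = _plane_normal(spec.plane_points)
        side = ((centers - spec.plane_points[0]) @ normal) >= 0
        return _split_by_labels(fp, side.astype(int), 2)

    if spec.rule == "vastus_intermedius_2x3":
        proximal, distal = _chord(fp, spec)
        axis = distal - proximal
        L = np.linalg.norm(axis)
        if L < 1e-9:
            raise DegenerateGeometryError("degenerate proximal-distal chord")
        if spec.mid_point is not None:
            mid = np.asarray(spec.mid_point, dtype=float)
        else:
            # midpoint between the medial and lateral edges: extremes along
            # the direction orthogonal to the chord within the best-fit plane
            _, plane_normal = fp.plane
            across = np.cross(axis / L, plane_normal)
            proj = fp.submesh.vertices @ across
            mid = (fp.submesh.vertices[proj.argmin()] + fp.submesh.vertices[proj.argmax()]) / 2.0
        half_normal = _plane_normal(np.array([proximal, distal, mid]))
        halves = ((centers - proximal) @ half_normal) >= 0
        t = (centers - proximal) @ (axis / L) / L
        thirds = np.clip(np.floor(t * 3).astype(int), 0, 2)
        labels = halves.astype(int) * 3 + thirds
        return _split_by_labels(fp, labels, 6)

    # thinnest_part
    proximal, distal = _chord(fp, spec)
    axis = distal - proximal
    L = np.linalg.norm(axis)
    if L < 1e-9:
        raise DegenerateGeometryError("degenerate proximal-distal chord")
    u = axis / L
    _, plane_normal_vec = fp.plane
    across = np.cross(u, plane_normal_vec)
    t = (centers - proximal) @ u / L
    w = (centers - proximal) @ across
    # scan interior cut positions; width = across-spread of faces in a slab
    candidates = np.linspace(0.2, 0.8, 25)
    slab = 0.05
    best_t, best_width = None, np.inf
    for tc in candidates:
        in_slab = np.abs(t - tc) <= slab
        if in_slab.sum() < 2:
            continue
        width = w[in_slab].max() - w[in_slab].min()
        if width < best_width:
            best_width, best_t = width, tc
    if best_t is None:
        raise SubdivisionError("thinnest-part scan found no valid cut position")
    return _split_by_labels(fp, (t >= best_t).astype(int), 2)
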