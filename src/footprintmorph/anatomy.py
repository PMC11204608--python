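"""Per-bone integral properties and femoral morphometrics in an ISB frame.

The femoral anatomical frame follows the International Society of
Biomechanics convention: origin at the transepicondylar-axis (TEA) midpoint,
y from the origin toward the femoral head center (cranial), z lateral in the
plane spanned by y and the epicondylar line, x = y x z (anterior).  Femoral
morphometrics: mechanical-axis length MA (head center to TEA midpoint),
TEA length, femoral head diameter FHD (least-squares sphere fit) and shaft
diameter SD (equal-area diameter of the mid-shaft cross-section).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import DegenerateGeometryError, EmptyInputError, OpenMeshError, ParameterError

__all__ = [
    "AnatomicalFrame",
    "BoneMetrics",
    "FemoralMorphometrics",
    "sphere_fit",
    "build_isb_frame",
    "bone_metrics",
    "measure_femur",
    "cross_section_area",
]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame (x anterior, y cranial, z lateral)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        M = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-9):
            raise DegenerateGeometryError("frame is not right-handed (x cross y != z)")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation: columns are the axes."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Express world points in frame coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.origin


@dataclass
class BoneMetrics:
    volume: float  # mm^3
    surface_area: float  # mm^2
    center_of_gravity: np.ndarray  # mm, in frame coordinates


@dataclass
class FemoralMorphometrics:
    MA: float  # mechanical-axis length, mm
    TEA: float  # transepicondylar-axis length, mm
    FHD: float  # femoral head diameter, mm
    SD: float  # shaft diameter, mm


def sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere through >= 4 non-coplanar points.

    Linearised normal equations: ``|p|^2 = 2 c . p + (r^2 - |c|^2)``.
    Returns ``(center, radius)``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 4 or points.shape[1] != 3:
        raise ParameterError("sphere_fit needs an (n >= 4, 3) point array")
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    # coplanar points leave the normal direction unconstrained -> rank < 4
    if np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-9 * max(1.0, np.abs(A).max())) < 3:
        raise DegenerateGeometryError("points are coplanar; sphere fit is degenerate")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced a non-positive radius")
    return center, float(np.sqrt(r2))


def build_isb_frame(
    head_center,
    epicondyle_medial,
    epicondyle_lateral,
    side: str = "right",
) -> AnatomicalFrame:
    """ISB femoral frame from the head center and the two epicondyles.

    Origin = epicondylar midpoint; y = unit vector origin -> head center;
    z = component of the epicondylar direction orthogonal to y, oriented
    laterally (the medial->lateral direction on either side, so the sign
    convention depends on ``side``); x = y x z points anteriorly.
    """
    if side not in ("left", "right"):
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    head = np.asarray(head_center, dtype=float)
    med = np.asarray(epicondyle_medial, dtype=float)
    lat = np.asarray(epicondyle_lateral, dtype=float)
    origin = (med + lat) / 2.0
    y = head - origin
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise DegenerateGeometryError("head center coincides with the TEA midpoint")
    y = y / ny
    epi = lat - med  # medial -> lateral: lateral on both sides
    z = epi - (epi @ y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-9 * np.linalg.norm(epi):
        raise DegenerateGeometryError("head center lies on the epicondylar line")
    z = z / nz
    x = np.cross(y, z)
    return AnatomicalFrame(origin, x, y, z)


def bone_metrics(mesh: trimesh.Trimesh, frame: AnatomicalFrame | None = None) -> BoneMetrics:
    """Volume, surface area and volume centroid of a bone mesh.

    Volume and centroid come from the divergence theorem over signed
    tetrahedra (requires a closed mesh); surface area is the triangle-area
    sum.  The centroid is reported in ``frame`` coordinates when a frame is
    given.  A consistently inward-oriented mesh is repaired (volume sign
    flipped) with a warning rather than rejected.
    """
    if len(mesh.faces) == 0:
        raise EmptyInputError("cannot compute metrics of an empty mesh")
    if not mesh.is_watertight:
        raise OpenMeshError("volume and centroid require a closed (watertight) mesh")
    volume = mesh.volume
    if volume < 0:
        warnings.warn("mesh was inward-oriented; repairing orientation", stacklevel=2)
        mesh = mesh.copy()
        mesh.invert()
        volume = mesh.volume
    cog = mesh.center_mass
    if frame is not None:
        cog = frame.to_frame(cog)
    return BoneMetrics(float(volume), float(mesh.area), np.asarray(cog, dtype=float))


def cross_section_area(mesh: trimesh.Trimesh, plane_origin, plane_normal) -> float:
    """Total enclosed area of the planar cross-section of a closed mesh.

    Loops are filled and unioned, so small spurious loops (segmentation
    specks) cannot double-count and interior voids are treated as solid.
    """
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    section = mesh.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if section is None:
        raise EmptyInputError("cross-section plane misses the mesh")
    planar, _ = section.to_2D()
    polys = []
    for loop in planar.discrete:
        if len(loop) >= 3:
            poly = Polygon(loop).buffer(0)
            if poly.area > 0:
                polys.append(poly)
    if not polys:
        raise EmptyInputError("cross-section contains no closed loop")
    return float(unary_union(polys).area)


def measure_femur(
    mesh: trimesh.Trimesh,
    landmarks: dict,
    frame: AnatomicalFrame | None = None,
    head_band_mm: float = 2.0,
) -> FemoralMorphometrics:
    """Femoral morphometrics MA, TEA, FHD, SD.

    ``landmarks`` must contain ``head_center`` (or ``head_points``),
    ``epicondyle_medial`` and ``epicondyle_lateral``.  FHD is the diameter
    of a least-squares sphere through the head-surface points (mesh vertices
    within ``head_band_mm`` of the closest-to-center shell when only the
    center is given).  SD is the equal-area diameter ``2 sqrt(A / pi)`` of
    the shaft cross-section at 50% of MA along the frame's y axis.
    """
    for key in ("epicondyle_medial", "epicondyle_lateral"):
        if key not in landmarks:
            raise ParameterError(f"landmarks must include {key!r}")
    med = np.asarray(landmarks["epicondyle_medial"], dtype=float)
    lat = np.asarray(landmarks["epicondyle_lateral"], dtype=float)
    tea = float(np.linalg.norm(med - lat))
    mid = (med + lat) / 2.0

    if "head_points" in landmarks:
        head_pts = np.asarray(landmarks["head_points"], dtype=float)
    elif "head_center" in landmarks:
        hc = np.asarray(landmarks["head_center"], dtype=float)
        d = np.linalg.norm(mesh.vertices - hc, axis=1)
        head_pts = mesh.vertices[d <= d.min() + head_band_mm]
    else:
        raise ParameterError("landmarks must include 'head_center' or 'head_points'")
    head_center_fit, head_radius = sphere_fit(head_pts)
    # trim points off the spherical shell (neck/junction contamination) and refit
    for _ in range(2):
        resid = np.abs(
            np.linalg.norm(head_pts - head_center_fit, axis=1) - head_radius
        )
        keep = resid <= max(3.0 * resid.std(), 0.05)
        if keep.sum() >= 4 and keep.sum() < len(head_pts):
            head_pts = head_pts[keep]
            head_center_fit, head_radius = sphere_fit(head_pts)
    fhd = 2.0 * head_radius

    head_center = np.asarray(landmarks.get("head_center", head_center_fit), dtype=float)
    ma = float(np.linalg.norm(head_center - mid))
    if not fhd < ma:
        raise DegenerateGeometryError("femoral head diameter must be smaller than MA")

    if frame is None:
        frame = build_isb_frame(head_center, med, lat)
    plane_origin = frame.from_frame([0.0, ma / 2.0, 0.0])
    area = cross_section_area(mesh, plane_origin, frame.y_axis)
    if area <= 0:
        raise EmptyInputError("mid-shaft cross-section is empty")
    sd = 2.0 * float(np.sqrt(area / np.pi))
    return FemoralMorphometrics(MA=ma, TEA=tea, FHD=fhd, SD=sd)
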