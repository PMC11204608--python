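"""Synthetic specimens: phantom bones, surface paint patches with analytic
ground truth, CT-like voxelization, and multi-specimen cohorts.

Every phantom bone is a union of implicit primitives (spheres and capsules),
which gives three things for free: an exact signed-distance function for CT
voxelization, a smooth triangulated surface via marching cubes of that SDF,
and parametric surfaces (sphere / cylinder barrel) on which paint patches
can be defined with *analytically known* area and centroid.  Paint regions
live in the isometric parametric coordinates of their host primitive (a
cylinder barrel unrolls isometrically to the plane; a spherical cap has a
closed-form area and centroid), so the ground truth is exact, not itself the
output of a mesh computation.

Cohorts emulate a small cadaveric study: per-specimen global size scaling,
log-normal between-specimen variation of patch areas with a requested CV,
positional jitter of patches on the bone, and left/right mirroring.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon
from skimage import measure

from .errors import ParameterError
from .segmentation import CTVolume
from .surfaces import RigidTransform

__all__ = [
    "Sphere",
    "Capsule",
    "CapRegion",
    "CylinderRegion",
    "SyntheticBone",
    "PaintPatch",
    "SyntheticScene",
    "GroundTruth",
    "DEFAULT_HU_MAP",
    "make_synthetic_bone",
    "make_paint_patch",
    "voxelize_scene",
    "make_cohort",
    "make_repeat_scans",
    "default_knee_scene_params",
    "build_scene",
]

DEFAULT_HU_MAP = {
    "air": -1000.0,
    "soft_tissue": 40.0,
    "cortical_bone": 1200.0,
    "paint": 2600.0,
}

_SDF_CHUNK = 500_000


# --------------------------------------------------------------------------
# implicit primitives


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ParameterError("sphere radius must be positive")

    def sdf(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points - self.center, axis=1) - self.radius

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance to the primitive's *surface* (unsigned outside, negative inside)."""
        return self.sdf(points)

    def normal(self, points: np.ndarray) -> np.ndarray:
        v = points - self.center
        n = np.linalg.norm(v, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return v / n

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.center - self.radius, self.center + self.radius])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Sphere":
        return Sphere(R @ self.center + t, self.radius)


@dataclass(frozen=True)
class Capsule:
    """Segment from ``a`` to ``b`` inflated by ``radius`` (rounded cylinder)."""

    a: np.ndarray
    b: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.radius <= 0:
            raise ParameterError("capsule radius must be positive")
        if np.allclose(self.a, self.b):
            raise ParameterError("capsule endpoints must differ")

    @property
    def axis_length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    @property
    def axis_dir(self) -> np.ndarray:
        return (self.b - self.a) / self.axis_length

    def _closest_axis(self, points: np.ndarray) -> np.ndarray:
        d = self.axis_dir
        t = np.clip((points - self.a) @ d, 0.0, self.axis_length)
        return self.a + t[:, None] * d[None, :]

    def sdf(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points - self._closest_axis(points), axis=1) - self.radius

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        return self.sdf(points)

    def normal(self, points: np.ndarray) -> np.ndarray:
        v = points - self._closest_axis(points)
        n = np.linalg.norm(v, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return v / n

    @property
    def bounds(self) -> np.ndarray:
        lo = np.minimum(self.a, self.b) - self.radius
        hi = np.maximum(self.a, self.b) + self.radius
        return np.array([lo, hi])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Capsule":
        return Capsule(R @ self.a + t, R @ self.b + t, self.radius)


# --------------------------------------------------------------------------
# paint regions on primitive surfaces


@dataclass(frozen=True)
class CapRegion:
    """Spherical cap: points of the host sphere within ``half_angle`` of ``axis``."""

    sphere: Sphere
    axis: np.ndarray
    half_angle: float  # radians

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", axis / np.linalg.norm(axis))
        if not 0 < self.half_angle < math.pi / 2:
            raise ParameterError("cap half-angle must be in (0, 90) degrees")

    @property
    def host(self) -> Sphere:
        return self.sphere

    def contains(self, points: np.ndarray) -> np.ndarray:
        v = points - self.sphere.center
        n = np.linalg.norm(v, axis=1)
        n[n == 0] = 1.0
        cosang = (v @ self.axis) / n
        return cosang >= math.cos(self.half_angle)

    @property
    def area(self) -> float:
        r = self.sphere.radius
        return 2.0 * math.pi * r * r * (1.0 - math.cos(self.half_angle))

    @property
    def centroid(self) -> np.ndarray:
        # surface centroid of a spherical cap lies on its axis at
        # r (1 + cos(theta)) / 2 from the center
        r = self.sphere.radius
        return self.sphere.center + self.axis * (r * (1.0 + math.cos(self.half_angle)) / 2.0)

    def surface_points(self, n: int = 20000):
        """Deterministic near-equal-area sample of the cap (points, weights)."""
        k = max(8, int(math.sqrt(n)))
        phi = (np.arange(k) + 0.5) / k * self.half_angle
        psi = (np.arange(k) + 0.5) / k * 2 * math.pi
        P, S = np.meshgrid(phi, psi, indexing="ij")
        w = np.sin(P).ravel()
        e1, e2 = _orthonormal_basis(self.axis)
        r = self.sphere.radius
        pts = (
            self.sphere.center
            + r * np.cos(P).ravel()[:, None] * self.axis
            + r * (np.sin(P) * np.cos(S)).ravel()[:, None] * e1
            + r * (np.sin(P) * np.sin(S)).ravel()[:, None] * e2
        )
        return pts, w

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "CapRegion":
        return CapRegion(self.sphere.transformed(R, t), R @ self.axis, self.half_angle)


@dataclass(frozen=True)
class CylinderRegion:
    """Region on a capsule barrel given as a polygon in unrolled coordinates.

    Coordinates are ``(t, s)``: ``t`` mm along the axis from endpoint ``a``,
    ``s = r * phi`` mm of arc from the reference direction.  The unrolling is
    an isometry, so the polygon's planar area *is* the surface area.
    """

    capsule: Capsule
    polygon: Polygon
    ref_dir: np.ndarray

    def __post_init__(self):
        d = self.capsule.axis_dir
        ref = np.asarray(self.ref_dir, dtype=float)
        ref = ref - (ref @ d) * d
        nrm = np.linalg.norm(ref)
        if nrm < 1e-12:
            raise ParameterError("ref_dir must not be parallel to the capsule axis")
        object.__setattr__(self, "ref_dir", ref / nrm)
        r = self.capsule.radius
        t0, s0, t1, s1 = self.polygon.bounds
        if s1 - s0 >= 2 * math.pi * r:
            raise ParameterError("patch arc width exceeds the host circumference")
        if t0 < -1e-9 or t1 > self.capsule.axis_length + 1e-9:
            raise ParameterError("patch extends beyond the host cylinder barrel")

    @property
    def host(self) -> Capsule:
        return self.capsule

    def _params(self, points: np.ndarray):
        d = self.capsule.axis_dir
        rel = points - self.capsule.a
        t = rel @ d
        e1 = self.ref_dir
        e2 = np.cross(d, e1)
        phi = np.arctan2(rel @ e2, rel @ e1)
        return t, phi * self.capsule.radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        t, s = self._params(points)
        return shapely.contains_xy(self.polygon, t, s)

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def centroid(self) -> np.ndarray:
        pts, w = self.surface_points()
        return np.average(pts, axis=0, weights=w)

    def surface_points(self, n: int = 20000):
        t0, s0, t1, s1 = self.polygon.bounds
        aspect = (t1 - t0) / max(s1 - s0, 1e-9)
        kt = max(8, int(math.sqrt(n * aspect)))
        ks = max(8, int(math.sqrt(n / aspect)))
        tt = t0 + (np.arange(kt) + 0.5) / kt * (t1 - t0)
        ss = s0 + (np.arange(ks) + 0.5) / ks * (s1 - s0)
        T, S = np.meshgrid(tt, ss, indexing="ij")
        inside = shapely.contains_xy(self.polygon, T.ravel(), S.ravel())
        T, S = T.ravel()[inside], S.ravel()[inside]
        d = self.capsule.axis_dir
        e1 = self.ref_dir
        e2 = np.cross(d, e1)
        r = self.capsule.radius
        phi = S / r
        pts = (
            self.capsule.a
            + T[:, None] * d
            + r * np.cos(phi)[:, None] * e1
            + r * np.sin(phi)[:, None] * e2
        )
        return pts, np.ones(len(pts))

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "CylinderRegion":
        # an improper R (mirror) flips the angular handedness; the polygon is
        # mirrored in s so membership follows the transformed geometry
        poly = self.polygon
        if np.linalg.det(R) < 0:
            poly = shapely.transform(poly, lambda xy: xy * np.array([1.0, -1.0]))
        return CylinderRegion(self.capsule.transformed(R, t), poly, R @ self.ref_dir)


def _orthonormal_basis(axis: np.ndarray):
    axis = np.asarray(axis, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


# --------------------------------------------------------------------------
# bones


@dataclass
class SyntheticBone:
    """Phantom bone: named implicit primitives + landmarks + lazy surface mesh."""

    name: str
    kind: str
    primitives: dict
    landmarks: dict
    mesh_pitch: float = 1.0
    side: str = "right"
    _mesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def sdf(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        out = np.full(len(points), np.inf)
        for prim in self.primitives.values():
            np.minimum(out, prim.sdf(points), out=out)
        return out

    @property
    def bounds(self) -> np.ndarray:
        bs = np.array([p.bounds for p in self.primitives.values()])
        return np.array([bs[:, 0].min(axis=0), bs[:, 1].max(axis=0)])

    @property
    def mesh(self) -> trimesh.Trimesh:
        """Marching-cubes surface of the SDF at ``mesh_pitch`` resolution."""
        if self._mesh is None:
            self._mesh = _mesh_from_sdf(self.sdf, self.bounds, self.mesh_pitch)
        return self._mesh

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "SyntheticBone":
        bone = SyntheticBone(
            name=self.name,
            kind=self.kind,
            primitives={k: p.transformed(R, t) for k, p in self.primitives.items()},
            landmarks={k: R @ np.asarray(v, float) + t for k, v in self.landmarks.items()},
            mesh_pitch=self.mesh_pitch,
            side=self.side,
        )
        if self._mesh is not None and np.linalg.det(R) > 0:
            bone._mesh = trimesh.Trimesh(
                vertices=self._mesh.vertices @ R.T + t,
                faces=self._mesh.faces.copy(),
                process=False,
            )
        return bone


def _mesh_from_sdf(sdf, bounds: np.ndarray, pitch: float) -> trimesh.Trimesh:
    lo = bounds[0] - 3 * pitch
    hi = bounds[1] + 3 * pitch
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    axes = [lo[i] + np.arange(shape[i]) * pitch for i in range(3)]
    grid = np.empty(shape, dtype=np.float32)
    # evaluate by z-slabs to bound memory
    X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
    flat_xy = np.stack([X.ravel(), Y.ravel()], axis=1)
    for k, z in enumerate(axes[2]):
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), z)])
        grid[:, :, k] = sdf(pts).reshape(shape[0], shape[1]).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    # discard degenerate specks marching cubes emits where the SDF hits 0.0
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: m.area)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    else:
        trimesh.repair.fix_normals(mesh)
    return mesh


_FEMUR_DEFAULTS = {
    "head_radius": 25.0,
    "shaft_radius": 17.85,
    "length": 405.0,  # mechanical-axis length: head center to TEA midpoint
    "tea_width": 91.65,
    "condyle_radius": 22.0,
}
_TIBFIB_DEFAULTS = {
    "length": 380.0,
    "shaft_radius": 14.0,
    "plateau_radius": 22.0,
    "fibula_radius": 6.0,
    "fibula_head_radius": 10.5,
}
_PATELLA_DEFAULTS = {"radius": 18.0}
_PELVIS_DEFAULTS = {
    "tuber_radius": 28.0,
    "acetabulum_radius": 32.0,
    "iliac_radius": 50.0,
}
_GENERIC_DEFAULTS = {"head_radius": 12.0, "shaft_radius": 6.0, "length": 60.0}


def make_synthetic_bone(
    kind: str,
    size_params: dict | None = None,
    seed: int = 0,
    name: str | None = None,
    side: str = "right",
    mesh_pitch: float = 1.0,
) -> SyntheticBone:
    """Build a phantom bone of the given kind in a canonical local frame.

    The frame follows the anatomical convention used downstream: y runs
    cranially along the bone, z laterally (for a right-side bone), x
    anteriorly.  For the femur the origin is the transepicondylar-axis (TEA)
    midpoint and the head center sits at ``(0, length, 0)``, so the
    mechanical-axis length equals ``length`` by construction.  ``side='left'``
    mirrors the bone about the sagittal (z = 0) plane.

    ``seed`` is kept for interface symmetry with the stochastic generators;
    bone construction itself is fully determined by its parameters.
    """
    del seed  # deterministic construction
    if side not in ("left", "right"):
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    defaults = {
        "femur": _FEMUR_DEFAULTS,
        "tibia_fibula": _TIBFIB_DEFAULTS,
        "patella": _PATELLA_DEFAULTS,
        "pelvis": _PELVIS_DEFAULTS,
        "generic": _GENERIC_DEFAULTS,
    }.get(kind)
    if defaults is None:
        raise ParameterError(f"unknown bone kind: {kind!r}")
    params = {**defaults, **(size_params or {})}
    unknown = set(params) - set(defaults)
    if unknown:
        raise ParameterError(f"unknown size parameters for {kind}: {sorted(unknown)}")
    for key, value in params.items():
        if value <= 0:
            raise ParameterError(f"{kind} parameter {key} must be positive, got {value}")

    if kind == "femur":
        hr, sr = params["head_radius"], params["shaft_radius"]
        length, tea, cr = params["length"], params["tea_width"], params["condyle_radius"]
        prims = {
            "head": Sphere([0.0, length, 0.0], hr),
            "shaft": Capsule([0.0, 15.0, 0.0], [0.0, length - 0.4 * hr, 0.0], sr),
            "condyle_lateral": Sphere([0.0, 0.0, tea / 2 - cr], cr),
            "condyle_medial": Sphere([0.0, 0.0, -(tea / 2 - cr)], cr),
        }
        landmarks = {
            "head_center": np.array([0.0, length, 0.0]),
            "epicondyle_lateral": np.array([0.0, 0.0, tea / 2]),
            "epicondyle_medial": np.array([0.0, 0.0, -tea / 2]),
        }
    elif kind == "tibia_fibula":
        L = params["length"]
        prims = {
            "plateau": Sphere([0.0, -20.0, 0.0], params["plateau_radius"]),
            "shaft": Capsule([0.0, -30.0, 0.0], [0.0, -L + 15.0, 0.0], params["shaft_radius"]),
            "fibula_head": Sphere([0.0, -32.0, 24.0], params["fibula_head_radius"]),
            "fibula_shaft": Capsule(
                [0.0, -38.0, 24.0], [0.0, -L + 35.0, 22.0], params["fibula_radius"]
            ),
        }
        landmarks = {
            "plateau_center": np.array([0.0, -20.0, 0.0]),
            "fibula_head_apex": np.array([0.0, -32.0 - params["fibula_head_radius"], 24.0]),
        }
    elif kind == "patella":
        prims = {"body": Sphere([0.0, 0.0, 0.0], params["radius"])}
        landmarks = {"patella_center": np.array([0.0, 0.0, 0.0])}
    elif kind == "pelvis":
        prims = {
            "ischial_tuberosity": Sphere([0.0, 0.0, 0.0], params["tuber_radius"]),
            "acetabulum": Sphere([0.0, 42.0, -28.0], params["acetabulum_radius"]),
            "iliac": Sphere([0.0, 100.0, -12.0], params["iliac_radius"]),
        }
        landmarks = {"ischial_tuberosity_center": np.array([0.0, 0.0, 0.0])}
    else:  # generic
        hr, sr, L = params["head_radius"], params["shaft_radius"], params["length"]
        prims = {
            "head": Sphere([0.0, L, 0.0], hr),
            "shaft": Capsule([0.0, 0.0, 0.0], [0.0, L - 0.5 * hr, 0.0], sr),
        }
        landmarks = {"head_center": np.array([0.0, L, 0.0])}

    bone = SyntheticBone(
        name=name or kind,
        kind=kind,
        primitives=prims,
        landmarks=landmarks,
        mesh_pitch=mesh_pitch,
        side="right",
    )
    if side == "left":
        M = np.diag([1.0, 1.0, -1.0])
        bone = bone.transformed(M, np.zeros(3))
        bone.side = "left"
    return bone


# --------------------------------------------------------------------------
# paint patches


@dataclass
class PaintPatch:
    """Paint mark adhering to a host bone surface with exact ground truth.

    ``truth_area``/``truth_centroid`` come from the region's parametric
    definition, not from any mesh.  Where the host primitive's surface is
    partly buried inside another primitive of the same bone (e.g. a shaft
    region running under the head), the ground truth covers only the
    *exposed* part — paint can only sit on actual bone surface.  The patch
    *mesh* is a thin shell offset ``shell_offset`` mm outward from the host
    bone surface (paint and bone interblend on real CT, so the painted area
    is defined on the bone surface itself while the shell marks where the
    paint sits).
    """

    name: str
    host_bone: str
    shape_class: str
    region: object
    bone: SyntheticBone = field(repr=False)
    shell_offset: float = 0.15
    paint_thickness: float = 1.2
    _mesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)
    _exposure: tuple | None = field(default=None, repr=False, compare=False)

    def _exposed(self):
        """(fraction, exposed points, weights) of the region's surface that
        lies on the bone boundary rather than buried in another primitive."""
        if self._exposure is None:
            pts, w = self.region.surface_points(20000)
            exposed = self.bone.sdf(pts) > -0.05
            total = float(w.sum())
            frac = float(w[exposed].sum()) / total if total > 0 else 0.0
            self._exposure = (frac, pts[exposed], w[exposed])
        return self._exposure

    @property
    def exposed_fraction(self) -> float:
        return self._exposed()[0]

    @property
    def truth_area(self) -> float:
        frac = self.exposed_fraction
        if frac >= 0.999:
            return float(self.region.area)
        return float(self.region.area) * frac

    @property
    def truth_centroid(self) -> np.ndarray:
        if self.exposed_fraction >= 0.999:
            return np.asarray(self.region.centroid, dtype=float)
        _, pts, w = self._exposed()
        return np.average(pts, axis=0, weights=w)

    @property
    def mesh(self) -> trimesh.Trimesh:
        """Thin outward-offset shell over the painted bone faces."""
        if self._mesh is None:
            bone_mesh = self.bone.mesh
            host = self.region.host
            centers = bone_mesh.triangles_center
            on_host = np.abs(host.surface_distance(centers)) <= 0.75 * self.bone.mesh_pitch
            selected = on_host & self.region.contains(centers)
            if not selected.any():
                raise ParameterError(
                    f"paint patch {self.name!r} covers no face of its host bone"
                )
            sub = bone_mesh.submesh([np.nonzero(selected)[0]], append=True)
            offset = host.normal(sub.vertices) * self.shell_offset
            self._mesh = trimesh.Trimesh(
                vertices=sub.vertices + offset, faces=sub.faces, process=False
            )
        return self._mesh

    def transformed(self, R: np.ndarray, t: np.ndarray, bone: SyntheticBone) -> "PaintPatch":
        return PaintPatch(
            name=self.name,
            host_bone=self.host_bone,
            shape_class=self.shape_class,
            region=self.region.transformed(R, t),
            bone=bone,
            shell_offset=self.shell_offset,
            paint_thickness=self.paint_thickness,
        )


def _rect_polygon(length: float, width: float, t_center: float, s_center: float) -> Polygon:
    hl, hw = length / 2.0, width / 2.0
    return Polygon(
        [
            (t_center - hl, s_center - hw),
            (t_center + hl, s_center - hw),
            (t_center + hl, s_center + hw),
            (t_center - hl, s_center + hw),
        ]
    )


def _blob_polygon(
    length: float, width: float, t_center: float, s_center: float, rng, n_vertices: int, irregularity: float
) -> Polygon:
    ang = np.sort(rng.uniform(0, 2 * math.pi, n_vertices))
    radii = 1.0 + irregularity * rng.uniform(-1.0, 1.0, n_vertices)
    xs = t_center + 0.5 * length * radii * np.cos(ang)
    ys = s_center + 0.5 * width * radii * np.sin(ang)
    poly = Polygon(np.column_stack([xs, ys])).buffer(0)
    if poly.geom_type != "Polygon" or poly.area <= 0:
        poly = _rect_polygon(length, width, t_center, s_center)
    return poly


def make_paint_patch(
    bone: SyntheticBone,
    shape_class: str,
    location_params: dict,
    seed: int = 0,
    name: str | None = None,
    shell_offset: float = 0.15,
    paint_thickness: float = 1.2,
) -> PaintPatch:
    """Define a paint patch on a host primitive of a phantom bone.

    shape_class:
      * ``cap`` — spherical cap on a sphere primitive; needs ``half_angle_deg``
        (< 90, no more than a hemisphere) and optionally ``axis``;
      * ``linear`` — elongated strip (aspect ratio >= 4) on a capsule barrel;
        needs ``length``, ``width``, ``t_center`` (mm along axis) and
        optionally ``phi_deg`` (angular position);
      * ``polygonal`` — irregular blob polygon in unrolled cylinder
        coordinates; same placement keys plus ``n_vertices``/``irregularity``
        (randomised via ``seed``).
    """
    if not 0 < shell_offset <= 0.3:
        raise ParameterError("shell_offset must be in (0, 0.3] mm")
    params = dict(location_params)
    prim_name = params.pop("primitive", None)
    if prim_name is None or prim_name not in bone.primitives:
        raise ParameterError(
            f"location_params must name a host primitive of {bone.name!r} "
            f"(one of {sorted(bone.primitives)})"
        )
    host = bone.primitives[prim_name]
    rng = np.random.default_rng(seed)

    if shape_class == "cap":
        if not isinstance(host, Sphere):
            raise ParameterError("cap patches require a sphere primitive")
        half_angle = math.radians(params.pop("half_angle_deg", 0.0))
        axis = np.asarray(params.pop("axis", [0.0, 1.0, 0.0]), dtype=float)
        if params:
            raise ParameterError(f"unknown cap parameters: {sorted(params)}")
        if half_angle <= 0:
            raise ParameterError("cap half_angle_deg must be positive")
        region = CapRegion(host, axis, half_angle)
    elif shape_class in ("linear", "polygonal"):
        if not isinstance(host, Capsule):
            raise ParameterError(f"{shape_class} patches require a capsule primitive")
        length = float(params.pop("length", 0.0))
        width = float(params.pop("width", 0.0))
        t_center = float(params.pop("t_center", host.axis_length / 2.0))
        phi_deg = float(params.pop("phi_deg", 0.0))
        if length <= 0 or width <= 0:
            raise ParameterError("patch length and width must be positive")
        if shape_class == "linear" and length / width < 4.0:
            raise ParameterError("linear patches must have aspect ratio >= 4")
        if length > host.axis_length:
            raise ParameterError("patch is longer than its host cylinder")
        n_vertices = int(params.pop("n_vertices", 10))
        irregularity = float(params.pop("irregularity", 0.25))
        clip_to_host = bool(params.pop("clip_to_host", False))
        if params:
            raise ParameterError(f"unknown {shape_class} parameters: {sorted(params)}")
        # reference direction at the patch's angular center keeps the
        # polygon away from the unrolling seam
        e1, e2 = _orthonormal_basis(host.axis_dir)
        phi = math.radians(phi_deg)
        ref = math.cos(phi) * e1 + math.sin(phi) * e2
        if shape_class == "linear":
            poly = _rect_polygon(length, width, t_center, 0.0)
        else:
            poly = _blob_polygon(length, width, t_center, 0.0, rng, n_vertices, irregularity)
        if clip_to_host:
            # paint cannot extend beyond the bone: clip to the barrel's
            # valid axial range and to one full wrap of the circumference
            from shapely.geometry import box as shapely_box

            r = host.radius
            valid = shapely_box(
                0.0, -math.pi * r * 0.98, host.axis_length, math.pi * r * 0.98
            )
            poly = poly.intersection(valid)
            if poly.is_empty or poly.geom_type != "Polygon" or poly.area <= 0:
                raise ParameterError("patch lies entirely outside its host barrel")
        region = CylinderRegion(host, poly, ref)
    else:
        raise ParameterError(f"unknown shape_class: {shape_class!r}")

    patch = PaintPatch(
        name=name or f"{shape_class}_patch",
        host_bone=bone.name,
        shape_class=shape_class,
        region=region,
        bone=bone,
        shell_offset=shell_offset,
        paint_thickness=paint_thickness,
    )
    if patch.exposed_fraction < 0.5:
        raise ParameterError(
            f"patch {patch.name!r} is mostly buried inside the bone "
            f"(exposed fraction {patch.exposed_fraction:.2f})"
        )
    return patch


# --------------------------------------------------------------------------
# scenes, volumes, cohorts


@dataclass
class SyntheticScene:
    """One synthetic specimen: bones, paint patches and named landmarks."""

    bones: list
    patches: list
    landmarks: dict
    rng_seed: int = 0
    side: str = "right"
    specimen: str = "specimen"

    @property
    def bone_meshes(self) -> dict:
        return {b.name: b.mesh for b in self.bones}

    def bone(self, name: str) -> SyntheticBone:
        for b in self.bones:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def bounds(self) -> np.ndarray:
        bs = np.array([b.bounds for b in self.bones])
        return np.array([bs[:, 0].min(axis=0), bs[:, 1].max(axis=0)])

    def transformed(self, transform: RigidTransform) -> "SyntheticScene":
        R, t = transform.rotation, transform.translation
        bones = [b.transformed(R, t) for b in self.bones]
        by_name = {b.name: b for b in bones}
        patches = [p.transformed(R, t, by_name[p.host_bone]) for p in self.patches]
        landmarks = {k: R @ np.asarray(v, float) + t for k, v in self.landmarks.items()}
        return SyntheticScene(
            bones, patches, landmarks, self.rng_seed, self.side, self.specimen
        )

    def mirrored(self) -> "SyntheticScene":
        """Reflect about the sagittal (z = 0) plane, swapping left/right."""
        M = np.diag([1.0, 1.0, -1.0])
        bones = [b.transformed(M, np.zeros(3)) for b in self.bones]
        for b in bones:
            b.side = "left" if b.side == "right" else "right"
        by_name = {b.name: b for b in bones}
        patches = [p.transformed(M, np.zeros(3), by_name[p.host_bone]) for p in self.patches]
        landmarks = {k: M @ np.asarray(v, float) for k, v in self.landmarks.items()}
        side = "left" if self.side == "right" else "right"
        return SyntheticScene(bones, patches, landmarks, self.rng_seed, side, self.specimen)


@dataclass
class GroundTruth:
    """Analytic truth for a cohort: per-patch areas/centroids and transforms."""

    areas: dict = field(default_factory=dict)  # (specimen, patch) -> mm^2
    centroids: dict = field(default_factory=dict)  # (specimen, patch) -> [x, y, z]
    bone_volumes: dict = field(default_factory=dict)  # (specimen, bone) -> mm^3
    bone_surface_areas: dict = field(default_factory=dict)
    scan_transforms: dict = field(default_factory=dict)  # (specimen, scan) -> 4x4 list
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        def _key(k):
            return "|".join(str(p) for p in k) if isinstance(k, tuple) else str(k)

        payload = {
            "areas": {_key(k): v for k, v in self.areas.items()},
            "centroids": {_key(k): list(map(float, v)) for k, v in self.centroids.items()},
            "bone_volumes": {_key(k): v for k, v in self.bone_volumes.items()},
            "bone_surface_areas": {_key(k): v for k, v in self.bone_surface_areas.items()},
            "scan_transforms": {
                _key(k): np.asarray(v, float).tolist() for k, v in self.scan_transforms.items()
            },
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)

        def _unkey(d, cast=float):
            return {tuple(k.split("|")): cast(v) for k, v in d.items()}

        gt = cls()
        gt.areas = _unkey(raw["areas"])
        gt.centroids = {
            tuple(k.split("|")): np.asarray(v, float) for k, v in raw["centroids"].items()
        }
        gt.bone_volumes = _unkey(raw.get("bone_volumes", {}))
        gt.bone_surface_areas = _unkey(raw.get("bone_surface_areas", {}))
        gt.scan_transforms = {
            tuple(k.split("|")): np.asarray(v, float) for k, v in raw.get("scan_transforms", {}).items()
        }
        gt.warnings = list(raw.get("warnings", []))
        return gt


def voxelize_scene(
    scene: SyntheticScene,
    spacing: float = 1.0,
    hu_map: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    soft_tissue_margin: float = 12.0,
    padding: float = 8.0,
    ground_truth: GroundTruth | None = None,
) -> CTVolume:
    """Render a scene into a CT-like HU volume.

    Voxel centers inside any bone get the cortical-bone HU; voxels in a
    paint shell (outside the bone, within ``paint_thickness`` of the host
    surface, inside the patch region) get the paint HU; voxels within
    ``soft_tissue_margin`` of a bone get soft tissue, the rest air.
    Additive Gaussian noise with the stated SD, deterministic per seed.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    hu = {**DEFAULT_HU_MAP, **(hu_map or {})}

    if not scene.bones:
        shape = (8, 8, 8)
        values = np.full(shape, hu["air"], dtype=np.float32)
        if noise_sd > 0:
            values += np.random.default_rng(seed).normal(0, noise_sd, shape).astype(np.float32)
        return CTVolume(values, [spacing] * 3, [0.0, 0.0, 0.0])

    for patch in scene.patches:
        if patch.paint_thickness < 2 * spacing:
            msg = (
                f"patch {patch.name!r}: paint shell ({patch.paint_thickness} mm) spans "
                f"fewer than 2 voxels at spacing {spacing} mm"
            )
            if ground_truth is not None:
                ground_truth.warnings.append(msg)

    lo = scene.bounds[0] - padding
    hi = scene.bounds[1] + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[i] + np.arange(shape[i]) * spacing for i in range(3)]
    values = np.empty(shape, dtype=np.float32)

    X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
    flat_xy = np.stack([X.ravel(), Y.ravel()], axis=1)
    patches_by_bone: dict[str, list[PaintPatch]] = {}
    for p in scene.patches:
        patches_by_bone.setdefault(p.host_bone, []).append(p)

    for k, z in enumerate(axes[2]):
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), z)])
        min_sdf = np.full(len(pts), np.inf)
        for bone in scene.bones:
            np.minimum(min_sdf, bone.sdf(pts), out=min_sdf)
        slab = np.where(
            min_sdf < 0,
            hu["cortical_bone"],
            np.where(min_sdf < soft_tissue_margin, hu["soft_tissue"], hu["air"]),
        ).astype(np.float32)
        outside = min_sdf >= 0
        for patch in scene.patches:
            host = patch.region.host
            hd = host.surface_distance(pts)
            in_shell = outside & (hd >= 0) & (hd <= patch.paint_thickness)
            if in_shell.any():
                in_shell[in_shell] &= patch.region.contains(pts[in_shell])
                slab[in_shell] = hu["paint"]
        values[:, :, k] = slab.reshape(shape[0], shape[1])

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values += rng.normal(0.0, noise_sd, values.shape).astype(np.float32)
    return CTVolume(values, [spacing] * 3, lo)


def default_knee_scene_params() -> dict:
    """Default synthetic knee specimen: femur, tibia/fibula and patella with
    six paint patches whose base areas echo reported cadaveric footprint
    means (a large polygonal wrap on the femoral shaft for the vastus
    intermedius origin, condylar caps, linear pes-anserine-style strips...).
    """
    return {
        "mesh_pitch": 1.0,
        "bones": [
            {"kind": "femur", "name": "femur"},
            {"kind": "tibia_fibula", "name": "tibia_fibula", "offset": [0.0, -26.0, 0.0]},
            {"kind": "patella", "name": "patella", "offset": [48.0, 15.0, 0.0]},
        ],
        "patches": [
            {
                "name": "vastus_intermedius_O",
                "bone": "femur",
                "shape_class": "polygonal",
                "location_params": {
                    "primitive": "shaft",
                    "t_center": 230.0,
                    "length": 160.0,
                    "width": 72.0,
                    "phi_deg": 10.0,
                    "irregularity": 0.18,
                },
            },
            {
                "name": "gastrocnemius_caput_mediale_O",
                "bone": "femur",
                "shape_class": "cap",
                "location_params": {
                    "primitive": "condyle_medial",
                    "axis": [0.3, 0.55, -0.8],
                    "half_angle_deg": 27.0,
                },
            },
            {
                "name": "biceps_femoris_caput_breve_O",
                "bone": "femur",
                "shape_class": "linear",
                "location_params": {
                    "primitive": "shaft",
                    "t_center": 95.0,
                    "length": 62.0,
                    "width": 9.5,
                    "phi_deg": 140.0,
                },
            },
            {
                "name": "patellar_tendon_I",
                "bone": "tibia_fibula",
                "shape_class": "polygonal",
                "location_params": {
                    "primitive": "shaft",
                    "t_center": 32.0,
                    "length": 30.0,
                    "width": 22.0,
                    "phi_deg": -70.0,
                    "irregularity": 0.2,
                },
            },
            {
                "name": "sartorius_I",
                "bone": "tibia_fibula",
                "shape_class": "linear",
                "location_params": {
                    "primitive": "shaft",
                    "t_center": 48.0,
                    "length": 52.0,
                    "width": 6.5,
                    "phi_deg": -175.0,
                },
            },
            {
                "name": "quadriceps_tendon_I",
                "bone": "patella",
                "shape_class": "cap",
                "location_params": {
                    "primitive": "body",
                    "axis": [-0.2, 1.0, 0.0],
                    "half_angle_deg": 42.0,
                },
            },
        ],
    }


def build_scene(
    scene_params: dict | None = None,
    seed: int = 0,
    specimen: str = "specimen_1",
    side: str = "right",
) -> SyntheticScene:
    """Assemble one synthetic specimen from a scene-parameter dictionary."""
    params = scene_params or default_knee_scene_params()
    pitch = params.get("mesh_pitch", 1.0)
    bones = []
    for spec in params["bones"]:
        bone = make_synthetic_bone(
            spec["kind"],
            spec.get("size_params"),
            seed=seed,
            name=spec.get("name"),
            mesh_pitch=spec.get("mesh_pitch", pitch),
        )
        offset = np.asarray(spec.get("offset", [0.0, 0.0, 0.0]), dtype=float)
        bones.append(bone.transformed(np.eye(3), offset))
    by_name = {b.name: b for b in bones}
    patches = []
    for i, spec in enumerate(params.get("patches", [])):
        patches.append(
            make_paint_patch(
                by_name[spec["bone"]],
                spec["shape_class"],
                spec["location_params"],
                seed=seed * 10007 + i,
                name=spec["name"],
                shell_offset=spec.get("shell_offset", 0.15),
                paint_thickness=spec.get("paint_thickness", 1.2),
            )
        )
    landmarks = {}
    for bone in bones:
        for key, value in bone.landmarks.items():
            landmarks[f"{bone.name}:{key}"] = np.asarray(value, dtype=float)
    scene = SyntheticScene(bones, patches, landmarks, rng_seed=seed, specimen=specimen)
    if side == "left":
        scene = scene.mirrored()
    return scene


def _scaled_location_params(spec: dict, scale: float, jitter_t: float, jitter_phi_deg: float) -> dict:
    """Scale a patch's linear dimensions by ``scale`` and jitter its position."""
    lp = dict(spec["location_params"])
    if spec["shape_class"] == "cap":
        theta = math.radians(lp["half_angle_deg"])
        # area of a cap scales with (1 - cos theta); solve for the scaled angle
        target = min(scale**2 * (1.0 - math.cos(theta)), 1.0 - 1e-6)
        lp["half_angle_deg"] = math.degrees(math.acos(1.0 - target))
        axis = np.asarray(lp.get("axis", [0.0, 1.0, 0.0]), dtype=float)
        e1, _ = _orthonormal_basis(axis)
        tilt = math.radians(jitter_phi_deg)
        axis = math.cos(tilt) * axis / np.linalg.norm(axis) + math.sin(tilt) * e1
        lp["axis"] = axis.tolist()
    else:
        lp["length"] = lp["length"] * scale
        lp["width"] = lp["width"] * scale
        lp["t_center"] = lp.get("t_center", 0.0) + jitter_t
        lp["phi_deg"] = lp.get("phi_deg", 0.0) + jitter_phi_deg
        lp["clip_to_host"] = True
    return lp


def make_cohort(
    n_specimens: int = 4,
    base_scene_params: dict | None = None,
    variation_params: dict | None = None,
    seed: int = 0,
) -> tuple[list[SyntheticScene], GroundTruth]:
    """Generate a cohort of synthetic specimens with controlled variation.

    Between-specimen patch areas are log-normal around the base area with
    the requested coefficient of variation (``area_cv``, as a fraction);
    patch positions are jittered on the bone surface with SD
    ``position_jitter_mm``; overall bone size varies log-normally with
    ``size_cv``.  By default one specimen in four is right-sided and the
    rest are mirrored to the left, echoing a three-left/one-right cohort.
    """
    if n_specimens < 2:
        raise ParameterError("a cohort needs at least 2 specimens")
    var = {
        "area_cv": 0.33,
        "position_jitter_mm": 3.0,
        "size_cv": 0.05,
        "sides": None,
        **(variation_params or {}),
    }
    for key in ("area_cv", "size_cv"):
        if var[key] < 0:
            raise ParameterError(f"{key} must be non-negative")
    base = base_scene_params or default_knee_scene_params()
    sides = var["sides"]
    if sides is None:
        # three left, one right per block of four
        sides = [("right" if i % 4 == 3 else "left") for i in range(n_specimens)]

    def lognormal_factor(rng, cv):
        if cv == 0:
            return 1.0
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))

    child_seeds = np.random.SeedSequence(seed).spawn(n_specimens)
    scenes = []
    truth = GroundTruth()
    for i in range(n_specimens):
        rng = np.random.default_rng(child_seeds[i])
        spec_name = f"specimen_{i + 1}"
        size_factor = lognormal_factor(rng, var["size_cv"])
        params = {"mesh_pitch": base.get("mesh_pitch", 1.0), "bones": [], "patches": []}
        for bspec in base["bones"]:
            scaled = dict(bspec)
            defaults = {
                "femur": _FEMUR_DEFAULTS,
                "tibia_fibula": _TIBFIB_DEFAULTS,
                "patella": _PATELLA_DEFAULTS,
                "pelvis": _PELVIS_DEFAULTS,
                "generic": _GENERIC_DEFAULTS,
            }[bspec["kind"]]
            sp = {k: v * size_factor for k, v in {**defaults, **(bspec.get("size_params") or {})}.items()}
            scaled["size_params"] = sp
            if "offset" in scaled:
                scaled["offset"] = [v * size_factor for v in scaled["offset"]]
            params["bones"].append(scaled)
        for pspec in base.get("patches", []):
            area_factor = lognormal_factor(rng, var["area_cv"])
            jt = float(rng.normal(0.0, var["position_jitter_mm"]))
            jphi = float(rng.normal(0.0, var["position_jitter_mm"]))  # degrees-scale jitter
            scaled = dict(pspec)
            scaled["location_params"] = _scaled_location_params(
                pspec, math.sqrt(area_factor) * size_factor, jt, jphi
            )
            params["patches"].append(scaled)
        # all specimens share the base seed so that seed-dependent patch
        # shapes are common and between-specimen variation comes only from
        # the explicit variation parameters (CV = 0 => identical areas)
        scene = build_scene(params, seed=seed, specimen=spec_name, side=sides[i])
        scenes.append(scene)
        for patch in scene.patches:
            truth.areas[(spec_name, patch.name)] = patch.truth_area
            truth.centroids[(spec_name, patch.name)] = patch.truth_centroid
    return scenes, truth


def make_repeat_scans(
    scene: SyntheticScene,
    n_scans: int = 2,
    rotation_sd_deg: float = 0.3,
    translation_sd_mm: float = 0.5,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
) -> list[tuple[SyntheticScene, RigidTransform]]:
    """Emulate repeat CT acquisitions: scan 1 is the reference pose; later
    scans receive a small random rigid perturbation (repositioning between
    dissection steps).  Returns ``(scene, applied_transform)`` pairs."""
    from .geometry import rotation_about_axis

    rng = np.random.default_rng(seed)
    out = [(scene, RigidTransform.identity())]
    for k in range(1, n_scans):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.normal(0.0, rotation_sd_deg))
        R = rotation_about_axis(axis, angle)
        t = rng.normal(0.0, translation_sd_mm, size=3)
        transform = RigidTransform(R, t)
        out.append((scene.transformed(transform), transform))
        if ground_truth is not None:
            ground_truth.scan_transforms[(scene.specimen, f"scan_{k + 1}")] = transform.matrix
    return out


def truth_bone_volume(bone: SyntheticBone, pitch: float = 0.5) -> float:
    """Voxel-counting volume of a phantom bone (independent of any mesh)."""
    lo = bone.bounds[0] - pitch
    hi = bone.bounds[1] + pitch
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    axes = [lo[i] + (np.arange(shape[i]) + 0.5) * pitch for i in range(3)]
    count = 0
    X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
    flat_xy = np.stack([X.ravel(), Y.ravel()], axis=1)
    for z in axes[2]:
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), z)])
        count += int((bone.sdf(pts) < 0).sum())
    return count * pitch**3
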