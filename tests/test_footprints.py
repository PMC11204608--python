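"""Footprint tracing, centroid, best-fit plane, breakthrough point and
subdivision rules."""

import numpy as np
import pytest
import trimesh

import footprintmorph as fm
from footprintmorph.errors import (
    DegenerateGeometryError,
    EmptyFootprintError,
    EmptyInputError,
    SubdivisionError,
)
from footprintmorph.footprints import Footprint, SubdivisionSpec, assign_footprints
from footprintmorph.geometry import rotation_about_axis, sample_surface
from footprintmorph.surfaces import RigidTransform
from footprintmorph.synthetic import make_paint_patch, make_synthetic_bone

from conftest import planar_grid_mesh


@pytest.fixture(scope="module")
def cap_setup(request):
    """25 mm femoral head with a 30 deg cap patch, traced."""
    bone = make_synthetic_bone("femur", mesh_pitch=1.0)
    patch = make_paint_patch(bone, "cap", {"primitive": "head", "half_angle_deg": 30.0})
    fp = fm.trace_contact_area(bone.mesh, patch.mesh, epsilon=0.5)
    return bone, patch, fp


def _patch_footprint(bone, patch):
    """Footprint directly from region membership (no tracing)."""
    centers = bone.mesh.triangles_center
    host = patch.region.host
    selected = np.abs(host.surface_distance(centers)) <= 0.75 * bone.mesh_pitch
    selected &= patch.region.contains(centers)
    return Footprint.from_faces(bone.mesh, np.nonzero(selected)[0], patch.name)


class TestTrace:
    def test_cap_area_within_three_percent_of_analytic(self, cap_setup):
        _, patch, fp = cap_setup
        assert fp.area == pytest.approx(526.1, rel=0.03)

    def test_cap_centroid_recovered(self, cap_setup):
        _, patch, fp = cap_setup
        assert np.linalg.norm(fp.centroid - patch.truth_centroid) < 1.0

    def test_displaced_paint_gives_empty_footprint_error(self, generic_bone):
        patch = make_paint_patch(generic_bone, "cap", {"primitive": "head", "half_angle_deg": 30.0})
        displaced = patch.mesh.copy()
        displaced.apply_translation([0.0, 10.0, 0.0])  # lift the mark off the bone
        with pytest.raises(EmptyFootprintError):
            fm.trace_contact_area(generic_bone.mesh, displaced, epsilon=0.5)

    def test_full_coverage_recovers_whole_sphere(self):
        """Paint shell over the entire sphere: footprint = full surface."""
        bone = make_synthetic_bone("patella", {"radius": 18.0}, mesh_pitch=0.8)
        mesh = bone.mesh
        shell = trimesh.Trimesh(
            vertices=mesh.vertices + 0.15 * mesh.vertex_normals, faces=mesh.faces, process=False
        )
        fp = fm.trace_contact_area(mesh, shell, epsilon=0.5)
        assert fp.area == pytest.approx(4 * np.pi * 18.0**2, rel=0.03)

    def test_area_monotone_in_epsilon(self, generic_bone):
        patch = make_paint_patch(generic_bone, "cap", {"primitive": "head", "half_angle_deg": 30.0})
        areas = [
            fm.trace_contact_area(generic_bone.mesh, patch.mesh, epsilon=e).area
            for e in (0.3, 0.5, 0.8, 1.2)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(areas, areas[1:]))

    def test_equivariant_under_joint_rigid_motion(self, generic_bone):
        patch = make_paint_patch(generic_bone, "cap", {"primitive": "head", "half_angle_deg": 30.0})
        move = RigidTransform(rotation_about_axis([1, 0, 1], 0.6), [12.0, -3.0, 7.0])
        fp0 = fm.trace_contact_area(generic_bone.mesh, patch.mesh, epsilon=0.5)
        fp1 = fm.trace_contact_area(
            move.apply_mesh(generic_bone.mesh), move.apply_mesh(patch.mesh), epsilon=0.5
        )
        assert fp1.area == pytest.approx(fp0.area, rel=1e-9)
        assert np.allclose(fp1.centroid, move.apply(fp0.centroid), atol=1e-6)

    def test_overlapping_marks_resolved_deterministically(self, generic_bone):
        """Two overlapping marks: contested faces go to the nearer paint,
        and each attachment still gets a non-empty footprint."""
        a = make_paint_patch(
            generic_bone, "linear",
            {"primitive": "shaft", "t_center": 25.0, "length": 30.0, "width": 7.0, "phi_deg": 0.0},
        )
        b = make_paint_patch(
            generic_bone, "linear",
            {"primitive": "shaft", "t_center": 32.0, "length": 30.0, "width": 7.0, "phi_deg": 18.0},
        )
        out = assign_footprints(generic_bone.mesh, {"alpha": a.mesh, "beta": b.mesh}, epsilon=0.5)
        assert set(out) == {"alpha", "beta"}
        shared = set(out["alpha"].face_indices.tolist()) & set(out["beta"].face_indices.tolist())
        assert not shared


class TestCentroidAndPlane:
    def test_planar_unit_square_centroid(self):
        fp = Footprint(planar_grid_mesh(8, 8, 1.0, 1.0))
        assert np.allclose(fp.centroid, [0.5, 0.5, 0.0], atol=1e-9)

    def test_symmetric_cap_centroid_on_axis(self, cap_setup):
        _, _, fp = cap_setup
        assert abs(fp.centroid[0]) < 0.2 and abs(fp.centroid[2]) < 0.2

    def test_centroid_matches_surface_sampling_oracle(self, generic_bone, rng):
        patch = make_paint_patch(
            generic_bone, "polygonal",
            {"primitive": "shaft", "t_center": 27.0, "length": 28.0, "width": 14.0}, seed=9,
        )
        fp = _patch_footprint(generic_bone, patch)
        pts, _ = sample_surface(fp.submesh, 100_000, rng)
        assert np.linalg.norm(fp.centroid - pts.mean(axis=0)) < 0.5

    def test_planar_patch_plane_contains_vertices(self):
        fp = Footprint(planar_grid_mesh(6, 6, 2.0, 1.0))
        point, normal = fp.plane
        assert np.abs((fp.submesh.vertices - point) @ normal).max() < 1e-9

    def test_cap_plane_normal_along_symmetry_axis(self, cap_setup):
        _, _, fp = cap_setup
        _, normal = fp.plane
        angle = np.degrees(np.arccos(abs(normal @ np.array([0.0, 1.0, 0.0]))))
        assert angle < 1.0

    def test_plane_normal_points_outward(self, cap_setup):
        _, _, fp = cap_setup
        _, normal = fp.plane
        assert normal @ np.array([0.0, 1.0, 0.0]) > 0  # cap faces +y, away from bone

    def test_collinear_zero_width_strip_degenerate(self):
        # faces along a line with (numerically) zero width
        verts = np.array([[t, 0.0, 0.0] for t in np.linspace(0, 10, 12)] + [[5.0, 1e-13, 0.0]])
        faces = np.array([[i, i + 1, 12] for i in range(11)])
        strip = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        fp = Footprint(strip)
        with pytest.raises((DegenerateGeometryError, EmptyInputError)):
            fp.plane  # noqa: B018 - property evaluation is the operation


class TestBreakthrough:
    def test_planar_patch_breakthrough_is_centroid(self):
        fp = Footprint(planar_grid_mesh(8, 8, 1.0, 1.0))
        assert np.allclose(fp.breakthrough_point, fp.centroid, atol=1e-9)
        assert not fp.breakthrough_fallback

    def test_cap_breakthrough_at_apex(self, cap_setup):
        """30 deg cap about +y on a 25 mm head: breakthrough = cap apex."""
        bone, _, fp = cap_setup
        apex = bone.landmarks["head_center"] + [0.0, 25.0, 0.0]
        assert np.linalg.norm(fp.breakthrough_point - apex) < 0.2
        assert not fp.breakthrough_fallback

    def test_annulus_falls_back_to_nearest_rim_point(self, generic_bone):
        """Ring-shaped footprint: the centroid's normal line misses the
        surface, so the nearest point on the ring is returned and flagged."""
        head = generic_bone.primitives["head"]
        centers = generic_bone.mesh.triangles_center
        v = centers - head.center
        d = np.linalg.norm(v, axis=1)
        ang = np.degrees(np.arccos(np.clip(v[:, 1] / np.maximum(d, 1e-12), -1, 1)))
        ring = (np.abs(d - head.radius) < 0.5) & (ang > 25.0) & (ang < 45.0)
        fp = Footprint.from_faces(generic_bone.mesh, np.nonzero(ring)[0], "ring")
        bp = fp.breakthrough_point
        assert fp.breakthrough_fallback
        # fallback point lies exactly on the footprint surface
        from footprintmorph.geometry import NearestSurface

        _, dist, _ = NearestSurface(fp.submesh).query(bp[None, :])
        assert dist[0] < 1e-6

    def test_breakthrough_always_on_surface(self, cap_setup):
        from footprintmorph.geometry import NearestSurface

        _, _, fp = cap_setup
        _, dist, _ = NearestSurface(fp.submesh).query(fp.breakthrough_point[None, :])
        assert dist[0] < 1e-6


class TestSubdivision:
    @pytest.fixture()
    def strip(self):
        """Uniform planar strip, long axis along y (60 x 8 mm)."""
        mesh = planar_grid_mesh(12, 90, 8.0, 60.0)
        return Footprint(mesh, "strip")

    def test_linear_thirds_of_uniform_strip(self, strip):
        children = fm.subdivide(strip, SubdivisionSpec("linear_thirds"))
        assert len(children) == 3
        for child in children:
            assert child.area == pytest.approx(strip.area / 3, rel=0.02)

    def test_children_partition_parent_exactly(self, strip):
        children = fm.subdivide(strip, SubdivisionSpec("linear_thirds"))
        assert sum(c.area for c in children) == pytest.approx(strip.area, abs=1e-9)
        all_faces = np.concatenate([c.face_indices for c in children])
        assert sorted(all_faces.tolist()) == sorted(strip.face_indices.tolist())

    def test_vastus_rule_yields_six_nonempty_parts(self, generic_bone):
        """A wide wrap patch split by the 2 x 3 rule (halving plane x thirds)."""
        patch = make_paint_patch(
            generic_bone, "polygonal",
            {"primitive": "shaft", "t_center": 27.0, "length": 34.0, "width": 22.0,
             "irregularity": 0.1},
            seed=2,
        )
        fp = _patch_footprint(generic_bone, patch)
        children = fm.subdivide(fp, SubdivisionSpec("vastus_intermedius_2x3"))
        assert len(children) == 6
        assert all(len(c.submesh.faces) > 0 for c in children)
        assert sum(c.area for c in children) == pytest.approx(fp.area, abs=1e-9)

    def test_plane_split(self, strip):
        spec = SubdivisionSpec(
            "plane_split",
            plane_points=[[0.0, 30.0, 0.0], [8.0, 30.0, 0.0], [4.0, 30.0, 5.0]],
        )
        children = fm.subdivide(strip, spec)
        assert len(children) == 2
        assert children[0].area + children[1].area == pytest.approx(strip.area, abs=1e-9)

    def test_thinnest_part_cuts_at_the_waist(self):
        """Hourglass-shaped planar patch: the cut lands near the narrow middle."""
        mesh = planar_grid_mesh(20, 80, 10.0, 40.0)
        centers = mesh.triangles_center
        half_width = 1.5 + 3.5 * np.abs(centers[:, 1] - 20.0) / 20.0
        keep = np.abs(centers[:, 0] - 5.0) <= half_width
        fp = Footprint.from_faces(mesh, np.nonzero(keep)[0], "hourglass")
        children = fm.subdivide(fp, SubdivisionSpec("thinnest_part"))
        assert len(children) == 2
        # both halves roughly balanced: cut in the middle third of the length
        ys = [c.centroid[1] for c in children]
        assert min(ys) < 20.0 < max(ys)
        assert children[0].area + children[1].area == pytest.approx(fp.area, abs=1e-9)

    def test_plane_missing_footprint_is_an_error(self, strip):
        spec = SubdivisionSpec(
            "plane_split",
            plane_points=[[0.0, 200.0, 0.0], [8.0, 200.0, 0.0], [4.0, 200.0, 5.0]],
        )
        with pytest.raises(SubdivisionError):
            fm.subdivide(strip, spec)
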