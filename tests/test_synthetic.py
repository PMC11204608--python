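"""Phantom generator: determinism, analytic ground truth, voxelization,
cohort variation calibration."""

import numpy as np
import pytest

import footprintmorph as fm
from footprintmorph.errors import ParameterError
from footprintmorph.synthetic import (
    GroundTruth,
    SyntheticScene,
    make_cohort,
    make_paint_patch,
    make_synthetic_bone,
    truth_bone_volume,
    voxelize_scene,
)


class TestBones:
    def test_same_seed_is_bit_identical(self):
        a = make_synthetic_bone("femur", seed=3, mesh_pitch=2.0)
        b = make_synthetic_bone("femur", seed=3, mesh_pitch=2.0)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.faces, b.mesh.faces)

    def test_femur_head_center_recovered_by_sphere_fit(self, femur_bone):
        """The head landmark is the center of the spherical head component."""
        head = femur_bone.primitives["head"]
        verts = femur_bone.mesh.vertices
        on_head = np.abs(head.surface_distance(verts)) < 0.3
        for name, prim in femur_bone.primitives.items():
            if name != "head":
                on_head &= prim.surface_distance(verts) > 0.5
        center, radius = fm.sphere_fit(verts[on_head])
        assert np.linalg.norm(center - femur_bone.landmarks["head_center"]) < 0.1
        assert abs(radius - 25.0) < 0.1

    def test_bone_mesh_is_closed_and_oriented(self, generic_bone, femur_bone):
        for bone in (generic_bone, femur_bone):
            assert bone.mesh.is_watertight
            assert bone.mesh.volume > 0

    def test_mesh_volume_matches_voxel_counting_oracle(self, generic_bone):
        oracle = truth_bone_volume(generic_bone, pitch=0.5)
        assert generic_bone.mesh.volume == pytest.approx(oracle, rel=0.02)

    def test_femur_volume_matches_voxel_counting_oracle(self, femur_bone):
        """Full femur (400 mm class) against the 0.5 mm counting oracle."""
        oracle = truth_bone_volume(femur_bone, pitch=0.5)
        assert femur_bone.mesh.volume == pytest.approx(oracle, rel=0.02)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ParameterError):
            make_synthetic_bone("femur", {"head_radius": -1.0})
        with pytest.raises(ParameterError):
            make_synthetic_bone("nope")

    def test_left_side_mirrors_sagittally(self):
        right = make_synthetic_bone("femur", seed=0, mesh_pitch=2.0)
        left = make_synthetic_bone("femur", seed=0, side="left", mesh_pitch=2.0)
        assert np.allclose(
            left.landmarks["epicondyle_lateral"],
            right.landmarks["epicondyle_lateral"] * [1, 1, -1],
        )


class TestPaintPatches:
    def test_cap_area_matches_analytic_formula(self, femur_bone):
        """Spherical cap, half-angle 30 deg on a 25 mm head: 2 pi r^2 (1 - cos t)."""
        patch = make_paint_patch(
            femur_bone, "cap", {"primitive": "head", "half_angle_deg": 30.0}
        )
        expected = 2 * np.pi * 25.0**2 * (1 - np.cos(np.radians(30.0)))
        assert patch.truth_area == pytest.approx(expected, rel=1e-12)
        assert patch.truth_area == pytest.approx(526.1, abs=0.1)

    def test_zero_extent_patch_rejected(self, generic_bone):
        with pytest.raises(ParameterError):
            make_paint_patch(generic_bone, "cap", {"primitive": "head", "half_angle_deg": 0.0})
        with pytest.raises(ParameterError):
            make_paint_patch(
                generic_bone,
                "linear",
                {"primitive": "shaft", "length": 0.0, "width": 0.0, "t_center": 20.0},
            )

    def test_cap_cannot_exceed_hemisphere(self, generic_bone):
        with pytest.raises(ParameterError):
            make_paint_patch(generic_bone, "cap", {"primitive": "head", "half_angle_deg": 95.0})

    def test_linear_needs_aspect_ratio_four(self, generic_bone):
        with pytest.raises(ParameterError):
            make_paint_patch(
                generic_bone,
                "linear",
                {"primitive": "shaft", "length": 10.0, "width": 5.0, "t_center": 20.0},
            )

    def test_strip_area_matches_surface_sampling_oracle(self):
        """60 x 8 mm strip on a 17.85 mm cylinder: ~480 mm^2, checked by
        counting uniform surface samples that land inside the region."""
        bone = make_synthetic_bone(
            "generic", {"head_radius": 10.0, "shaft_radius": 17.85, "length": 100.0},
            mesh_pitch=5.0,  # mesh not needed; coarse pitch keeps it lazy-cheap
        )
        patch = make_paint_patch(
            bone,
            "linear",
            {"primitive": "shaft", "length": 60.0, "width": 8.0, "t_center": 47.0},
        )
        assert patch.truth_area == pytest.approx(480.0, rel=1e-12)
        cap = bone.primitives["shaft"]
        rng = np.random.default_rng(0)
        n = 200_000
        # uniform samples on the cylinder barrel (isometric parameterisation)
        t = rng.uniform(0, cap.axis_length, n)
        phi = rng.uniform(-np.pi, np.pi, n)
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.cross(cap.axis_dir, e1)
        pts = (
            cap.a
            + t[:, None] * cap.axis_dir
            + cap.radius * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        barrel_area = 2 * np.pi * cap.radius * cap.axis_length
        mc_area = patch.region.contains(pts).mean() * barrel_area
        assert mc_area == pytest.approx(patch.truth_area, rel=0.01)

    def test_patch_shell_adheres_to_bone_surface(self, generic_bone):
        patch = make_paint_patch(
            generic_bone, "cap", {"primitive": "head", "half_angle_deg": 30.0}
        )
        d = generic_bone.primitives["head"].surface_distance(patch.mesh.vertices)
        assert np.all(d > 0) and np.all(d <= 0.5)

    def test_truth_centroid_inside_patch_bounding_box(self, generic_bone):
        for shape, params in [
            ("cap", {"primitive": "head", "half_angle_deg": 40.0}),
            ("polygonal", {"primitive": "shaft", "t_center": 27.0, "length": 25.0, "width": 12.0}),
        ]:
            patch = make_paint_patch(generic_bone, shape, params, seed=5)
            lo, hi = patch.mesh.bounds
            assert np.all(patch.truth_centroid >= lo - 0.5)
            assert np.all(patch.truth_centroid <= hi + 0.5)


class TestVoxelization:
    def test_sphere_phantom_voxel_count(self):
        """Voxels at or above 250 HU recover the analytic sphere volume."""
        bone = make_synthetic_bone("patella", {"radius": 20.0})
        vol = voxelize_scene(SyntheticScene([bone], [], {}, 0), spacing=1.0, seed=1)
        count = int((vol.values >= 250).sum())
        assert count * 1.0 == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.03)

    def test_empty_scene_is_all_air(self):
        vol = voxelize_scene(SyntheticScene([], [], {}, 0), spacing=1.0)
        assert np.all(vol.values == -1000.0)

    def test_noise_is_deterministic_per_seed(self):
        bone = make_synthetic_bone("patella", {"radius": 10.0})
        scene = SyntheticScene([bone], [], {}, 0)
        a = voxelize_scene(scene, spacing=2.0, noise_sd=50.0, seed=9)
        b = voxelize_scene(scene, spacing=2.0, noise_sd=50.0, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_coarse_spacing_records_warning(self):
        bone = make_synthetic_bone("generic", mesh_pitch=3.0)
        patch = make_paint_patch(bone, "cap", {"primitive": "head", "half_angle_deg": 30.0})
        gt = GroundTruth()
        voxelize_scene(SyntheticScene([bone], [patch], {}, 0), spacing=2.0, ground_truth=gt)
        assert any("fewer than 2 voxels" in w for w in gt.warnings)


class TestCohort:
    def test_zero_cv_gives_identical_areas(self):
        scenes, gt = make_cohort(
            3, variation_params={"area_cv": 0.0, "size_cv": 0.0, "position_jitter_mm": 0.0},
            seed=5,
        )
        for patch in {k[1] for k in gt.areas}:
            vals = [gt.areas[(s.specimen, patch)] for s in scenes]
            assert np.ptp(vals) < 1e-9

    def test_requested_cv_is_realised_at_large_n(self):
        """Log-normal area variation: empirical CV within 5 points of 33%."""
        scenes, gt = make_cohort(
            200,
            variation_params={"area_cv": 0.33, "size_cv": 0.0, "position_jitter_mm": 0.0},
            seed=7,
        )
        for patch in {k[1] for k in gt.areas}:
            vals = np.array([gt.areas[(f"specimen_{i + 1}", patch)] for i in range(200)])
            cv = vals.std(ddof=0) / vals.mean()
            assert abs(cv - 0.33) < 0.05

    def test_cohort_deterministic_and_sided(self):
        s1, g1 = make_cohort(4, seed=11)
        s2, g2 = make_cohort(4, seed=11)
        assert g1.to_json() == g2.to_json()
        assert [s.side for s in s1] == ["left", "left", "left", "right"]

    def test_negative_cv_rejected(self):
        with pytest.raises(ParameterError):
            make_cohort(4, variation_params={"area_cv": -0.1})

    def test_ground_truth_json_round_trip(self):
        _, gt = make_cohort(2, seed=3)
        back = GroundTruth.from_json(gt.to_json())
        for key, val in gt.areas.items():
            assert back.areas[key] == pytest.approx(val, abs=1e-9)
        for key, val in gt.centroids.items():
            assert np.allclose(back.centroids[key], val, atol=1e-9)
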