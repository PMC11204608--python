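"""Rigid registration, surface deviation and coherent-model construction."""

import numpy as np
import pytest
import trimesh

import footprintmorph as fm
from footprintmorph.errors import DegenerateGeometryError
from footprintmorph.geometry import (
    NearestSurface,
    kabsch,
    rotation_about_axis,
    sample_surface,
)
from footprintmorph.surfaces import RigidTransform

from conftest import planar_grid_mesh


@pytest.fixture(scope="module")
def asymmetric_shape():
    """Sphere + offset box: no rotational symmetry, so ICP has a unique optimum."""
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    box = trimesh.creation.box(extents=[30, 20, 12])
    box.apply_translation([18.0, 0.0, 0.0])
    return trimesh.util.concatenate([sphere, box])


class TestRigidTransform:
    def test_composition_matches_direct_transform(self):
        a = RigidTransform(rotation_about_axis([0, 0, 1], 0.3), [1.0, 2.0, 3.0])
        b = RigidTransform(rotation_about_axis([1, 1, 0], -0.2), [-4.0, 0.5, 2.0])
        pts = np.random.default_rng(0).normal(size=(50, 3))
        assert np.allclose(b.compose(a).apply(pts), b.apply(a.apply(pts)), atol=1e-9)

    def test_inverse_round_trip(self):
        t = RigidTransform(rotation_about_axis([1, 2, 3], 0.7), [5.0, -1.0, 2.0])
        pts = np.random.default_rng(1).normal(size=(20, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_kabsch_collinear_configuration_rejected(self):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(src, src + 1.0)


class TestRigidAlign:
    def test_recovers_known_rotation_and_translation(self, asymmetric_shape):
        """10 deg about z + (5, -3, 2) mm recovered within 0.05 deg / 0.05 mm."""
        R = rotation_about_axis([0, 0, 1], np.radians(10.0))
        t = np.array([5.0, -3.0, 2.0])
        moving = trimesh.Trimesh(
            vertices=asymmetric_shape.vertices @ R.T + t, faces=asymmetric_shape.faces
        )
        recovered = fm.rigid_align(moving, asymmetric_shape, n_samples=1500, seed=0)
        rot_err = np.degrees(
            np.arccos(np.clip((np.trace(recovered.rotation @ R) - 1) / 2, -1, 1))
        )
        pt_err = np.linalg.norm(
            recovered.apply(moving.vertices) - asymmetric_shape.vertices, axis=1
        ).max()
        assert rot_err < 0.05
        assert pt_err < 0.05

    def test_identity_for_identical_meshes(self, asymmetric_shape):
        recovered = fm.rigid_align(asymmetric_shape, asymmetric_shape, n_samples=800, seed=0)
        assert np.allclose(recovered.rotation, np.eye(3), atol=1e-6)
        assert np.linalg.norm(recovered.translation) < 1e-6

    def test_landmark_initialisation_handles_large_offsets(self, asymmetric_shape):
        R = rotation_about_axis([1, 1, 1], np.radians(60.0))
        t = np.array([40.0, -25.0, 15.0])
        moving = trimesh.Trimesh(
            vertices=asymmetric_shape.vertices @ R.T + t, faces=asymmetric_shape.faces
        )
        src = moving.vertices[[0, 200, 400, 600]]
        dst = asymmetric_shape.vertices[[0, 200, 400, 600]]
        recovered = fm.rigid_align(
            moving, asymmetric_shape, init_landmarks=(src, dst), n_samples=800, seed=0
        )
        pt_err = np.linalg.norm(
            recovered.apply(moving.vertices) - asymmetric_shape.vertices, axis=1
        ).max()
        assert pt_err < 0.05

    def test_noise_floor(self, asymmetric_shape):
        """Vertex noise SD 0.2 mm leaves a residual mean distance < 0.3 mm."""
        rng = np.random.default_rng(7)
        noisy = trimesh.Trimesh(
            vertices=asymmetric_shape.vertices + rng.normal(0, 0.2, (len(asymmetric_shape.vertices), 3)),
            faces=asymmetric_shape.faces,
        )
        recovered = fm.rigid_align(noisy, asymmetric_shape, n_samples=1000, seed=1)
        pts, _ = sample_surface(noisy, 2000, np.random.default_rng(2))
        _, d, _ = NearestSurface(asymmetric_shape).query(recovered.apply(pts))
        assert d.mean() < 0.3

    def test_collinear_landmarks_rejected(self, asymmetric_shape):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            fm.rigid_align(asymmetric_shape, asymmetric_shape, init_landmarks=(src, src))


class TestDeviation:
    def test_identical_meshes_have_zero_deviation(self, icosphere):
        dev = fm.deviation_analysis(icosphere, icosphere, n_samples=2000, seed=0)
        assert dev.mean == pytest.approx(0.0, abs=1e-9)
        assert dev.std == pytest.approx(0.0, abs=1e-9)

    def test_parallel_plane_offset(self):
        test = planar_grid_mesh(10, 10, 1.0, 1.0, z=0.5)
        reference = planar_grid_mesh(30, 30, 3.0, 3.0, z=0.0)
        reference.apply_translation([-1.0, -1.0, 0.0])  # test plane inside overlap
        dev = fm.deviation_analysis(test, reference, n_samples=3000, seed=1)
        assert dev.mean == pytest.approx(0.5, abs=1e-9)

    def test_offset_spheres_match_brute_force_oracle(self):
        """Concentric spheres r=20.5 vs 20: mean ~0.5 mm, cross-checked
        against exhaustive point-to-every-triangle distances."""
        reference = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
        test = trimesh.creation.icosphere(subdivisions=3, radius=20.5)
        dev = fm.deviation_analysis(test, reference, n_samples=800, seed=3)
        assert dev.mean == pytest.approx(0.5, rel=0.02)
        pts, _ = sample_surface(test, 200, np.random.default_rng(3))
        tri = reference.triangles.view(np.ndarray)
        brute = np.array(
            [
                np.linalg.norm(
                    trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1))) - p,
                    axis=1,
                ).min()
                for p in pts
            ]
        )
        _, fast, _ = NearestSurface(reference).query(pts)
        assert np.abs(fast - brute).max() < 1e-9

    def test_deviation_invariant_under_common_rigid_motion(self, icosphere):
        test = trimesh.creation.icosphere(subdivisions=3, radius=20.7)
        ref = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
        d0 = fm.deviation_analysis(test, ref, n_samples=1000, seed=5)
        move = RigidTransform(rotation_about_axis([1, 0, 2], 0.8), [10.0, -4.0, 6.0])
        d1 = fm.deviation_analysis(move.apply_mesh(test), move.apply_mesh(ref), n_samples=1000, seed=5)
        assert d1.mean == pytest.approx(d0.mean, rel=1e-6)

    def test_sampling_stability_at_large_n(self, icosphere):
        test = trimesh.creation.icosphere(subdivisions=3, radius=20.5)
        a = fm.deviation_analysis(test, icosphere, n_samples=50000, seed=10)
        b = fm.deviation_analysis(test, icosphere, n_samples=50000, seed=11)
        assert abs(a.mean - b.mean) / a.mean < 0.02


class TestMergeAndClean:
    def test_half_spheres_weld_into_closed_sphere(self, icosphere):
        fc = icosphere.triangles_center
        top = icosphere.submesh([np.nonzero(fc[:, 2] >= 0)[0]], append=True)
        bottom = icosphere.submesh([np.nonzero(fc[:, 2] < 0)[0]], append=True)
        merged = fm.merge_and_clean([top, bottom], smoothing_iters=0)
        assert merged.is_watertight
        assert merged.volume == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.02)

    def test_no_smoothing_is_identity_up_to_welding(self, icosphere):
        merged = fm.merge_and_clean([icosphere], smoothing_iters=0)
        assert len(merged.faces) == len(icosphere.faces)
        assert merged.area == pytest.approx(icosphere.area, abs=1e-9)

    def test_small_holes_are_closed(self, icosphere):
        # punch a vertex-star hole (all faces around one vertex): simple rim
        star = np.any(icosphere.faces == 10, axis=1)
        holey = icosphere.submesh([np.nonzero(~star)[0]], append=True)
        assert not holey.is_watertight
        merged = fm.merge_and_clean([holey], smoothing_iters=0)
        assert merged.is_watertight

    def test_smoothing_improves_fidelity_of_noisy_surface(self, icosphere):
        rng = np.random.default_rng(4)
        noisy = trimesh.Trimesh(
            vertices=icosphere.vertices + rng.normal(0, 0.3, (len(icosphere.vertices), 3)),
            faces=icosphere.faces,
        )
        before = fm.deviation_analysis(noisy, icosphere, n_samples=3000, seed=6).mean
        smoothed = fm.merge_and_clean([noisy], smoothing_iters=20)
        after = fm.deviation_analysis(smoothed, icosphere, n_samples=3000, seed=6).mean
        assert after < before

    def test_smoothing_conserves_volume(self, icosphere):
        smoothed = fm.merge_and_clean([icosphere], smoothing_iters=30)
        assert abs(smoothed.volume - icosphere.volume) / icosphere.volume < 0.01

    def test_disjoint_fragments_warn(self, icosphere):
        far = icosphere.copy()
        far.apply_translation([100.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            merged = fm.merge_and_clean([icosphere, far], smoothing_iters=0)
        assert merged.body_count == 2
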