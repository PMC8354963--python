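"""Rigid-transform algebra, Kabsch step, initialization and ICP behaviour."""

from __future__ import annotations

import json

import numpy as np
import pytest
import trimesh

from conftest import random_blob_mesh
from sinusid.distance import nearest_point_distances, rms_of
from sinusid.registration import (
    RigidTransform,
    apply_transform,
    best_fit_transform,
    icp_register,
    initial_align,
)


def random_rigid(rng: np.random.Generator, max_angle=np.pi / 6, max_trans=20.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, max_angle)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, rng.uniform(-max_trans, max_trans, size=3))


class TestRigidTransform:
    def test_rejects_improper_rotations(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))  # not orthogonal

    def test_inverse_and_compose(self):
        rng = np.random.default_rng(3)
        t = random_rigid(rng)
        pts = rng.normal(size=(50, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)
        composed = t.compose(t.inverse())
        assert np.allclose(composed.as_matrix(), np.eye(4), atol=1e-9)

    def test_matrix_round_trip(self):
        t = random_rigid(np.random.default_rng(9))
        back = RigidTransform.from_matrix(t.as_matrix())
        assert np.allclose(back.rotation, t.rotation)
        assert np.allclose(back.translation, t.translation)


class TestBestFit:
    def test_identity_for_identical_points(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        t = best_fit_transform(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)

    def test_recovers_exact_generator(self):
        rng = np.random.default_rng(1)
        src = rng.normal(size=(30, 3)) * 10
        truth = random_rigid(rng)
        t = best_fit_transform(src, truth.apply(src))
        assert np.allclose(t.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(t.translation, truth.translation, atol=1e-9)

    def test_noisy_fit_matches_rotation_grid_oracle(self):
        """Least-squares residual equals brute-force search over rotations."""
        rng = np.random.default_rng(7)
        src = rng.normal(size=(4, 3)) * 5
        tgt = random_rigid(rng, max_angle=0.3, max_trans=2.0).apply(src)
        tgt += rng.normal(scale=0.3, size=tgt.shape)
        t = best_fit_transform(src, tgt)
        res_fit = np.sqrt(((t.apply(src) - tgt) ** 2).sum())

        # oracle: dense grid over rotation angles (x-y-z Euler), optimal
        # translation in closed form (centroid match) for each rotation
        best = np.inf
        angles = np.linspace(-0.5, 0.5, 41)
        mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
        for ax in angles:
            Rx = trimesh.transformations.rotation_matrix(ax, [1, 0, 0])[:3, :3]
            for ay in angles:
                Ry = trimesh.transformations.rotation_matrix(ay, [0, 1, 0])[:3, :3]
                for az in angles:
                    Rz = trimesh.transformations.rotation_matrix(az, [0, 0, 1])[:3, :3]
                    R = Rz @ Ry @ Rx
                    moved = (src - mu_s) @ R.T + mu_t
                    best = min(best, np.sqrt(((moved - tgt) ** 2).sum()))
        assert res_fit <= best + 1e-3

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            best_fit_transform(line, line)
        with pytest.raises(ValueError):
            best_fit_transform(np.zeros((2, 3)), np.zeros((2, 3)))


class TestInitialAlign:
    def test_self_alignment_is_identity(self):
        mesh = random_blob_mesh(0)
        t = initial_align(mesh, mesh)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0.0, atol=1e-9)

    def test_pure_translation_recovered(self):
        mesh = random_blob_mesh(1)
        moved = mesh.copy()
        moved.vertices = moved.vertices + np.array([5.0, -3.0, 2.0])
        t = initial_align(moved, mesh)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(t.translation, [-5.0, 3.0, -2.0], atol=1e-6)

    def test_known_rotation_recovered(self):
        mesh = random_blob_mesh(2)
        angle = np.deg2rad(25.0)
        R = trimesh.transformations.rotation_matrix(angle, [0, 0, 1])[:3, :3]
        moved = mesh.copy()
        moved.vertices = moved.vertices @ R.T
        t = initial_align(moved, mesh)
        # recovered rotation must undo the applied one
        assert np.allclose(t.rotation @ R, np.eye(3), atol=1e-6)

    def test_collinear_vertices_rejected(self):
        line = trimesh.Trimesh(
            vertices=np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)]),
            faces=[[0, 1, 2], [1, 2, 3]],
            process=False,
        )
        with pytest.raises(ValueError):
            initial_align(line, line)


class TestICP:
    def test_self_registration_identity_one_iteration(self):
        mesh = random_blob_mesh(3)
        report = icp_register(mesh, mesh)
        assert report.iterations == 1
        assert report.converged
        assert report.final_rms < 1e-9
        assert np.allclose(report.transform.as_matrix(), np.eye(4), atol=1e-9)

    def test_recovers_random_rigid_displacement(self):
        """A displaced copy registers back to exact overlap."""
        mesh = random_blob_mesh(4)
        rng = np.random.default_rng(42)
        truth = random_rigid(rng, max_angle=np.deg2rad(30), max_trans=20.0)
        moved = apply_transform(mesh, truth)
        report = icp_register(moved, mesh)
        assert report.converged
        assert report.final_rms < 1e-6
        full = rms_of(nearest_point_distances(apply_transform(moved, report.transform), mesh))
        assert full < 1e-6

    def test_trace_non_increasing_on_random_pairs(self):
        """The ICP objective never increases, across 100 seeded random pairs."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = random_blob_mesh(2 * seed, n_sub=1)
            b = random_blob_mesh(2 * seed + 1, n_sub=1)
            moved = apply_transform(a, random_rigid(rng))
            report = icp_register(moved, b, max_iterations=25, tolerance_mm=1e-5)
            assert np.all(np.diff(report.objective_trace) <= 1e-12)

    def test_result_invariant_under_rigid_pretransform(self, sinus_pair):
        a, b = sinus_pair
        base = icp_register(a, b, sample_size=1500, seed=0)
        pre = random_rigid(np.random.default_rng(5))
        report = icp_register(apply_transform(a, pre), b, sample_size=1500, seed=0)
        assert abs(report.final_rms - base.final_rms) < 5e-3

    def test_distinct_shapes_final_not_above_initial(self, sinus_mismatch_pair):
        a, b = sinus_mismatch_pair
        report = icp_register(a, b, sample_size=1500, seed=0, tolerance_mm=3e-3)
        assert report.converged
        assert report.objective_trace[-1] <= report.objective_trace[0] + 1e-12

    def test_invalid_params_rejected(self, sinus_pair):
        a, b = sinus_pair
        with pytest.raises(ValueError):
            icp_register(a, b, max_iterations=0)
        with pytest.raises(ValueError):
            icp_register(a, b, tolerance_mm=0.0)

    def test_report_json_round_trip(self, tmp_path):
        mesh = random_blob_mesh(6)
        report = icp_register(mesh, mesh)
        payload = json.loads(report.to_json(tmp_path / "report.json"))
        assert np.allclose(payload["matrix"], np.eye(4), atol=1e-9)
        assert payload["converged"] is True


def test_apply_transform_preserves_faces_and_volume(cube10):
    t = random_rigid(np.random.default_rng(8))
    moved = apply_transform(cube10, t)
    assert np.array_equal(moved.faces, cube10.faces)
    assert moved.volume == pytest.approx(cube10.volume, rel=1e-9)
    back = apply_transform(moved, t.inverse())
    assert np.allclose(back.vertices, cube10.vertices, atol=1e-9)
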