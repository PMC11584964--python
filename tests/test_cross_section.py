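"""Tooth-frame estimation and plane sectioning, with a brute-force oracle."""

import numpy as np
import pytest

from conftest import fast_spec, random_convex_mesh
from periomesh import (
    AmbiguousAxisError,
    EmptySectionError,
    LabeledMesh,
    RigidTransform,
    ToothFrame,
    estimate_tooth_frame,
    section_mesh,
)
from periomesh.mesh_model import CROWN, GINGIVA, OTHER
from periomesh.synthetic_scan import generate_phantom_pair


def brute_force_section_length(mesh: LabeledMesh, frame: ToothFrame) -> float:
    """Independent oracle: sum of per-triangle plane-intersection lengths."""
    total = 0.0
    n = frame.section_normal
    for tri in mesh.vertices[mesh.faces]:
        d = (tri - frame.origin) @ n
        d = np.where(d == 0.0, 1e-12, d)
        pts = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            if d[i] * d[j] < 0:
                t = d[i] / (d[i] - d[j])
                pts.append(tri[i] + t * (tri[j] - tri[i]))
        if len(pts) == 2:
            total += float(np.linalg.norm(pts[1] - pts[0]))
    return total


class TestEstimateToothFrame:
    def test_phantom_axis_is_z(self, fast_pair):
        mesh0, _, truth = fast_pair
        frame = estimate_tooth_frame(mesh0)
        frame.validate()
        angle = np.degrees(np.arccos(np.clip(frame.axis @ truth.frame.axis, -1, 1)))
        assert angle < 0.5  # coronal orientation included

    def test_equivariance_under_rigid_motion(self, fast_pair):
        mesh0, _, _ = fast_pair
        g = RigidTransform.from_axis_angle([1, 0.2, -0.4], 35, (5, -2, 3))
        hint = np.array([1.0, 0.0, 0.0])
        f0 = estimate_tooth_frame(mesh0, azimuth_hint=hint)
        f1 = estimate_tooth_frame(
            mesh0.transformed(g.rotation, g.translation),
            azimuth_hint=g.rotation @ hint,
        )
        np.testing.assert_allclose(f1.origin, g.apply(f0.origin[None])[0],
                                   atol=0.01)
        assert np.degrees(np.arccos(np.clip(
            f1.axis @ (g.rotation @ f0.axis), -1, 1))) < 0.5
        assert np.degrees(np.arccos(np.clip(
            f1.section_normal @ (g.rotation @ f0.section_normal), -1, 1))) < 0.5

    def test_collinear_crown_raises(self):
        v = np.column_stack([np.zeros(10), np.zeros(10), np.linspace(0, 5, 10)])
        v = np.vstack([v, [[1.0, 0.0, -1.0]]])
        labels = np.array([CROWN] * 10 + [GINGIVA])
        mesh = LabeledMesh(v, np.empty((0, 3), dtype=int), labels)
        with pytest.raises(AmbiguousAxisError):
            estimate_tooth_frame(mesh)

    def test_degenerate_top_eigenvalues_need_hint(self):
        # flat square plate: two equal leading eigenvalues
        g = np.linspace(-1, 1, 12)
        xx, yy = np.meshgrid(g, g)
        v = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        v = np.vstack([v, [[0.0, 0.0, -1.0]]])
        labels = np.array([CROWN] * xx.size + [GINGIVA])
        mesh = LabeledMesh(v, np.empty((0, 3), dtype=int), labels)
        with pytest.raises(AmbiguousAxisError, match="hint"):
            estimate_tooth_frame(mesh)
        frame = estimate_tooth_frame(mesh, azimuth_hint=[0.0, 1.0, 0.0])
        frame.validate()

    def test_hint_defines_section_normal(self, fast_pair):
        mesh0, _, _ = fast_pair
        frame = estimate_tooth_frame(mesh0, azimuth_hint=[1.0, 0.0, 0.0])
        # normal = hint orthogonalised against the axis
        assert abs(frame.section_normal @ frame.axis) < 1e-9
        assert frame.section_normal[0] > 0.99


class TestSectionMesh:
    def test_cube_midplane_perimeter(self, unit_cube):
        frame = ToothFrame([0, 0, 0], [1, 0, 0], [0, 0, 1.0])
        sec = section_mesh(unit_cube, frame)
        assert sec.is_closed
        assert sec.length() == pytest.approx(4.0, abs=1e-9)
        oracle = brute_force_section_length(unit_cube, frame)
        assert sec.length() == pytest.approx(oracle, abs=1e-9)

    def test_plane_missing_mesh_raises(self, unit_cube):
        frame = ToothFrame([0, 0, 5.0], [1, 0, 0], [0, 0, 1.0])
        with pytest.raises(EmptySectionError):
            section_mesh(unit_cube, frame)

    def test_single_triangle_off_plane(self):
        v = np.array([[0, 0, 1], [1, 0, 1], [0, 1, 1.0]])
        mesh = LabeledMesh(v, [[0, 1, 2]], np.full(3, OTHER))
        frame = ToothFrame([0, 0, 0], [1, 0, 0], [0, 0, 1.0])
        with pytest.raises(EmptySectionError):
            section_mesh(mesh, frame)

    @pytest.mark.parametrize("seed", range(10))
    def test_length_oracle_on_random_convex_meshes(self, seed):
        rng = np.random.default_rng(seed)
        mesh = random_convex_mesh(rng)
        center = mesh.vertices.mean(axis=0)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        axis = np.cross(normal, [0.123, 0.456, 0.789])
        axis /= np.linalg.norm(axis)
        frame = ToothFrame(center, axis, normal)
        sec = section_mesh(mesh, frame)
        assert sec.length() == pytest.approx(
            brute_force_section_length(mesh, frame), abs=1e-9
        )

    def test_points_lie_on_plane(self, fast_pair):
        mesh0, _, truth = fast_pair
        sec = section_mesh(mesh0, truth.frame)
        resid = (sec.points3d - truth.frame.origin) @ truth.frame.section_normal
        assert np.abs(resid).max() < 1e-9

    def test_phantom_margin_height_matches_truth(self, fast_pair):
        mesh0, _, truth = fast_pair
        sec = section_mesh(mesh0, truth.frame)
        g = (sec.labels == GINGIVA) & (sec.points2d[:, 0] > 0)
        v_top = sec.points2d[g, 1].max()
        # truth frame origin is at the margin level, so v(z_margin0) = 0
        assert abs(v_top - truth.z_margin0) < truth.spec.mesh_resolution

    def test_vertex_order_invariance(self, unit_cube):
        frame = ToothFrame([0, 0, 0], [1, 0, 0], [0, 0, 1.0])
        ref = section_mesh(unit_cube, frame)
        rng = np.random.default_rng(3)
        perm = rng.permutation(unit_cube.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = LabeledMesh(
            unit_cube.vertices[perm], inv[unit_cube.faces],
            unit_cube.labels[perm],
        )
        sec = section_mesh(shuffled, frame)
        assert sec.length() == pytest.approx(ref.length(), abs=1e-12)
        # same point set up to ordering
        a = np.sort(np.round(ref.points2d, 9).view("f8").reshape(-1, 2), axis=0)
        b = np.sort(np.round(sec.points2d, 9).view("f8").reshape(-1, 2), axis=0)
        np.testing.assert_array_equal(a, b)

    def test_orientation_coronal_last(self, fast_pair):
        mesh0, _, truth = fast_pair
        sec = section_mesh(mesh0, truth.frame)
        if not sec.is_closed:
            assert sec.points2d[-1, 1] >= sec.points2d[0, 1]
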