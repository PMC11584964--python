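"""P1/P2/P3 margin construction: point rules, oracle equivalence, recovery."""

import numpy as np
import pytest

from conftest import fast_spec
from periomesh import (
    MissingGingivaError,
    NoIntersectionError,
    SectionPolyline,
    estimate_tooth_frame,
    find_sulcus_point,
    intersect_horizontal,
    measure_tooth,
    section_mesh,
)
from periomesh.margin_metrics import horizontal_crossings
from periomesh.mesh_model import CROWN, GINGIVA, OTHER
from periomesh.synthetic_scan import generate_phantom_pair


def polyline(points, labels=None, frame="STL0") -> SectionPolyline:
    points = np.asarray(points, dtype=float)
    if labels is None:
        labels = [GINGIVA] * len(points)
    return SectionPolyline(
        plane_origin=np.zeros(3), plane_normal=np.array([0.0, 0.0, 1.0]),
        axis=np.array([0.0, 1.0, 0.0]), points2d=points,
        labels=np.asarray(labels), source_frame=frame,
    )


class TestFindSulcusPoint:
    def test_single_gingiva_point(self):
        sec = polyline([(0.5, 1.0), (0.9, 4.2)], [CROWN, GINGIVA])
        assert find_sulcus_point(sec) == (0.9, 4.2)

    def test_tie_breaks_toward_axis(self):
        sec = polyline([(1.0, 4.2), (0.8, 4.2)])
        assert find_sulcus_point(sec) == (0.8, 4.2)

    def test_no_gingiva_raises(self):
        sec = polyline([(0, 0), (1, 1)], [CROWN, OTHER])
        with pytest.raises(MissingGingivaError):
            find_sulcus_point(sec)

    def test_min_u_restricts_side(self):
        sec = polyline([(-2.0, 9.0), (1.0, 4.0)])
        assert find_sulcus_point(sec, min_u=0.0) == (1.0, 4.0)

    def test_phantom_margin_recovery(self, fast_pair):
        mesh0, _, truth = fast_pair
        sec = section_mesh(mesh0, truth.frame)
        u, v = find_sulcus_point(sec, min_u=0.0)
        assert abs(v - truth.z_margin0) < truth.spec.mesh_resolution
        assert abs(u - truth.p1[0]) < truth.spec.mesh_resolution


class TestIntersectHorizontal:
    def test_interpolation_on_one_segment(self):
        sec = polyline([(0.0, 0.0), (0.0, 2.0)])
        assert intersect_horizontal(sec, 1.0, 0.0) == (0.0, 1.0)

    def test_nearest_crossing_wins(self):
        sec = polyline([(0.5, 0.0), (0.5, 2.0), (3.0, 2.0), (3.0, 0.0)])
        assert intersect_horizontal(sec, 1.0, 0.6) == (0.5, 1.0)
        assert intersect_horizontal(sec, 1.0, 2.5) == (3.0, 1.0)

    def test_no_crossing_raises(self):
        sec = polyline([(0.0, 0.0), (1.0, 0.5)])
        with pytest.raises(NoIntersectionError):
            intersect_horizontal(sec, 2.0, 0.0)

    def test_exact_vertex_crossing_counts_once(self):
        sec = polyline([(0.0, 0.0), (1.0, 1.0), (2.0, 0.0)])
        us = horizontal_crossings(sec, 1.0)
        assert len(us) == 1 and us[0] == pytest.approx(1.0)

    def test_brute_force_crossing_oracle_100_polylines(self):
        """Interpolated crossings equal an exhaustive per-segment scan."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = np.column_stack([rng.uniform(-3, 3, 30),
                                   rng.uniform(-2, 2, 30)])
            sec = polyline(pts)
            level = float(rng.uniform(-1.5, 1.5))
            u_ref = float(rng.uniform(-3, 3))

            brute = []
            for (ua, va), (ub, vb) in zip(pts[:-1], pts[1:]):
                if (va - level) * (vb - level) < 0:
                    t = (level - va) / (vb - va)
                    brute.append(ua + t * (ub - ua))
            brute.extend(pts[np.abs(pts[:, 1] - level) <= 1e-12, 0])
            if not brute:
                with pytest.raises(NoIntersectionError):
                    intersect_horizontal(sec, level, u_ref)
                continue
            best = min(sorted(brute), key=lambda u: abs(u - u_ref))
            u, v = intersect_horizontal(sec, level, u_ref)
            assert v == level
            assert u == pytest.approx(best, abs=1e-9)


class TestMeasureTooth:
    def test_identical_sections_measure_zero(self, fast_pair):
        mesh0, _, truth = fast_pair
        sec = section_mesh(mesh0, truth.frame)
        m = measure_tooth(sec, sec)
        assert m.height_loss == 0.0
        assert m.width_loss == 0.0

    def test_mismatched_planes_rejected(self, fast_pair):
        mesh0, _, truth = fast_pair
        sec = section_mesh(mesh0, truth.frame)
        other = polyline([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="plane"):
            measure_tooth(sec, other)

    def test_noiseless_phantom_exact(self):
        spec = fast_spec(delta_h=0.3, delta_w=0.5, mesh_resolution=0.05)
        mesh0, mesh1, truth = generate_phantom_pair(spec)
        frame = estimate_tooth_frame(mesh0, azimuth_hint=[1.0, 0.0, 0.0])
        m = measure_tooth(section_mesh(mesh0, frame), section_mesh(mesh1, frame))
        assert m.height_loss == pytest.approx(truth.height_loss, abs=0.02)
        assert m.width_loss == pytest.approx(0.5, abs=0.02)
        assert m.height_loss_axial == pytest.approx(0.3, abs=0.02)
        # invariants of the construction itself
        assert m.p3[1] == pytest.approx(m.p2[1], abs=1e-9)
        assert m.height_loss >= abs(m.height_loss_axial) - 1e-9

    def test_pure_width_change(self):
        spec = fast_spec(delta_h=0.0, delta_w=0.4)
        mesh0, mesh1, truth = generate_phantom_pair(spec)
        frame = estimate_tooth_frame(mesh0, azimuth_hint=[1.0, 0.0, 0.0])
        m = measure_tooth(section_mesh(mesh0, frame), section_mesh(mesh1, frame))
        assert m.width_loss == pytest.approx(0.4, abs=0.02)
        assert m.height_loss == pytest.approx(truth.height_loss, abs=0.02)

    def test_noisy_mean_recovery_20_seeds(self):
        """Mean recovered width over 20 noisy replicates near delta_w."""
        ws, hs = [], []
        for seed in range(20):
            spec = fast_spec(noise_sd=0.02, seed=seed)
            mesh0, mesh1, truth = generate_phantom_pair(spec)
            frame = estimate_tooth_frame(mesh0, azimuth_hint=[1.0, 0.0, 0.0])
            m = measure_tooth(section_mesh(mesh0, frame),
                              section_mesh(mesh1, frame))
            ws.append(m.width_loss)
            hs.append(m.height_loss)
        assert abs(np.mean(ws) - 0.5) < 0.05
        assert abs(np.mean(hs) - 0.3) < 0.05

    def test_rigid_motion_invariance(self, fast_pair):
        from periomesh import RigidTransform

        mesh0, mesh1, truth = fast_pair
        g = RigidTransform.from_axis_angle([0.2, 1, 0.5], 40, (4, -1, 2))
        hint = np.array([1.0, 0.0, 0.0])

        f = estimate_tooth_frame(mesh0, azimuth_hint=hint)
        m = measure_tooth(section_mesh(mesh0, f), section_mesh(mesh1, f))

        m0g = mesh0.transformed(g.rotation, g.translation)
        m1g = mesh1.transformed(g.rotation, g.translation)
        fg = estimate_tooth_frame(m0g, azimuth_hint=g.rotation @ hint)
        mg = measure_tooth(section_mesh(m0g, fg), section_mesh(m1g, fg))

        assert mg.height_loss == pytest.approx(m.height_loss, abs=1e-6)
        assert mg.width_loss == pytest.approx(m.width_loss, abs=1e-6)
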