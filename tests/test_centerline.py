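"""Resampling, bifurcation decomposition and mesh-based extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import archssm as a
from archssm.centerline import (Centerline, clip_ad, decompose_and_resample,
                                extract_centerline, find_bifurcation_origin,
                                resample_centerline)
from archssm.errors import (DecompositionError, LandmarkError, ParameterError,
                            SegmentError)
from archssm.synthetic import centerline_to_tube_mesh


def _straight(n, length, radius=2.0, direction=(0, 0, 1.0), origin=(0, 0, 0)):
    d = np.asarray(direction, float) / np.linalg.norm(direction)
    t = np.linspace(0, length, n)
    return Centerline(np.asarray(origin, float) + np.outer(t, d),
                      np.full(n, radius))


class TestResample:
    def test_straight_segment_uniform_positions(self):
        line = _straight(5, 10.0)
        out = resample_centerline(line, 3)
        np.testing.assert_allclose(out.points[:, 2], [0.0, 5.0, 10.0],
                                   atol=1e-12)

    def test_idempotent_on_uniform_input(self):
        # equal-chord polyline (circle arc sampled at uniform angles)
        theta = np.linspace(0, np.pi, 30)
        pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta),
                               np.linspace(0, 5, 30)])
        line = Centerline(pts, np.linspace(1.0, 2.0, 30))
        again = resample_centerline(line, 30)
        np.testing.assert_allclose(again.points, line.points, atol=1e-9)
        np.testing.assert_allclose(again.radius, line.radius, atol=1e-9)

    @given(n=st.integers(min_value=2, max_value=60),
           length=st.floats(min_value=0.5, max_value=100.0))
    def test_count_and_endpoint_preservation(self, n, length):
        line = _straight(7, length)
        out = resample_centerline(line, n)
        assert out.n_points == n
        np.testing.assert_allclose(out.points[0], line.points[0], atol=1e-9)
        np.testing.assert_allclose(out.points[-1], line.points[-1], atol=1e-9)
        steps = np.diff(out.points[:, 2])
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(SegmentError):
            resample_centerline(_straight(5, 10.0), 1)


class TestBifurcationOrigin:
    def _diverging_pair(self, n_shared=21, radius=1.5):
        # identical for n_shared points, then diverging > 2x radius/step
        shared = np.column_stack([np.zeros(n_shared), np.zeros(n_shared),
                                  np.arange(n_shared, dtype=float)])
        step = 4.0 * radius
        ta = shared[-1] + np.cumsum(
            np.tile([step, 0, step], (10, 1)), axis=0)
        tb = shared[-1] + np.cumsum(
            np.tile([-step, 0, step], (10, 1)), axis=0)
        la = Centerline(np.vstack([shared, ta]), np.full(n_shared + 10, radius))
        lb = Centerline(np.vstack([shared, tb]), np.full(n_shared + 10, radius))
        return la, lb

    def test_constructed_divergence_index(self):
        la, lb = self._diverging_pair(n_shared=21)
        origin, (ia, jb) = find_bifurcation_origin(la, lb)
        # lines are identical for points 0..20, so the last co-contained
        # pair is at index 20 +- 1
        assert abs(ia - 20) <= 1
        assert abs(jb - 20) <= 1
        np.testing.assert_allclose(origin, la.points[ia], atol=1.5)

    def test_identical_lines_error(self):
        la, _ = self._diverging_pair()
        with pytest.raises(DecompositionError, match="diverge"):
            find_bifurcation_origin(la, la.copy())

    def test_disjoint_starts_error(self):
        la, lb = self._diverging_pair()
        lb.points = lb.points + np.array([50.0, 0, 0])
        with pytest.raises(DecompositionError):
            find_bifurcation_origin(la, lb)

    def test_generator_truth(self, clean_arch):
        """On a synthetic arch the merged origin lands near the true one."""
        p, arch = clean_arch
        # build the two "extracted" lines from the generator's segments
        dao_rev = Centerline(arch.dao.points[::-1], arch.dao.radius[::-1])
        la = Centerline(np.vstack([dao_rev.points, arch.ad.points[::-1][1:]]),
                        np.concatenate([dao_rev.radius,
                                        arch.ad.radius[::-1][1:]]))
        lb = Centerline(np.vstack([dao_rev.points, arch.aao.points[::-1][1:]]),
                        np.concatenate([dao_rev.radius,
                                        arch.aao.radius[::-1][1:]]))
        origin, _ = find_bifurcation_origin(la, lb)
        tol = max(la.radius.max(), lb.radius.max())
        assert np.linalg.norm(origin - arch.bifurcation_origin) < tol


class TestDecompose:
    def test_counts_and_origin_endpoints(self, clean_arch):
        p, arch = clean_arch
        dao_rev = Centerline(arch.dao.points[::-1], arch.dao.radius[::-1])
        la = Centerline(np.vstack([dao_rev.points, arch.ad.points[::-1][1:]]),
                        np.concatenate([dao_rev.radius,
                                        arch.ad.radius[::-1][1:]]))
        lb = Centerline(np.vstack([dao_rev.points, arch.aao.points[::-1][1:]]),
                        np.concatenate([dao_rev.radius,
                                        arch.aao.radius[::-1][1:]]))
        rec = decompose_and_resample(la, lb, (25, 25, 51))
        assert rec.counts == (25, 25, 51)
        assert rec.n_points == 101
        rec.validate(counts=(25, 25, 51))
        # each segment's junction endpoint is exactly the origin
        np.testing.assert_allclose(rec.aao.points[-1], rec.bifurcation_origin)
        np.testing.assert_allclose(rec.ad.points[-1], rec.bifurcation_origin)
        np.testing.assert_allclose(rec.dao.points[0], rec.bifurcation_origin)


class TestExtraction:
    def test_cylinder_axis_and_radius(self, cylinder_mesh):
        cl = extract_centerline(cylinder_mesh, np.array([0, 0, 5.0]),
                                np.array([0, 0, 55.0]), pitch=0.7)
        off_axis = np.linalg.norm(cl.points[:, :2], axis=1)
        assert off_axis.max() < 0.3
        interior = (cl.points[:, 2] > 8) & (cl.points[:, 2] < 52)
        np.testing.assert_allclose(cl.radius[interior], 3.0, atol=0.3)
        assert cl.length == pytest.approx(50.0, rel=0.02)

    def test_curved_tube_arc_length(self):
        # quarter-torus tube, centerline radius 20 mm
        t = np.linspace(0, np.pi / 2, 80)
        pts = np.column_stack([20 * np.cos(t), 20 * np.sin(t), np.zeros_like(t)])
        line = Centerline(pts, np.full(80, 2.5))
        from archssm.synthetic import _sweep_tube

        mesh = _sweep_tube(line, 20)
        cl = extract_centerline(mesh, pts[4], pts[-5], pitch=0.6)
        true_len = 20 * (t[-5] - t[4])
        assert cl.length == pytest.approx(true_len, rel=0.05)

    def test_landmark_outside_mesh(self, cylinder_mesh):
        with pytest.raises(LandmarkError):
            extract_centerline(cylinder_mesh, np.array([40.0, 0, 30.0]),
                               np.array([0, 0, 55.0]), pitch=0.8)


class TestClip:
    def test_zero_radius_returns_mesh_unchanged(self, cylinder_mesh):
        out = clip_ad(cylinder_mesh, np.array([0, 0, 30.0]), clip_radius=0.0)
        assert len(out.faces) == len(cylinder_mesh.faces)

    def test_far_outside_center_warns(self, cylinder_mesh):
        with pytest.warns(UserWarning, match="outside"):
            out = clip_ad(cylinder_mesh, np.array([100.0, 0, 0]),
                          clip_radius=2.0)
        assert len(out.faces) == len(cylinder_mesh.faces)

    def test_clip_blocks_the_duct_route(self, clean_arch):
        """After clipping, the aortic extraction goes over the arch."""
        p, arch = clean_arch
        mesh, lms = centerline_to_tube_mesh(arch, 20)
        clipped = clip_ad(mesh, lms["ad_medial"])
        line = extract_centerline(clipped, lms["dao_diaphragm"],
                                  lms["aao_rpa"], pitch=0.7)
        local_r = p.r_ad * (1 + p.duct_aneurysm_amp)
        d = np.linalg.norm(line.points - lms["ad_medial"], axis=1)
        assert d.min() > 1.5 * local_r
        # length matches the aortic route, not the ductal shortcut
        assert line.length == pytest.approx(p.dao_length + p.aao_length,
                                            rel=0.05)


class TestEndToEndMesh:
    def test_extraction_recovers_generator_segments(self, clean_arch):
        """Full two-pass protocol: mean point error < 10% of local radius."""
        from scipy.spatial import cKDTree

        p, arch = clean_arch
        mesh, lms = centerline_to_tube_mesh(arch, 20)
        line_ad = extract_centerline(mesh, lms["dao_diaphragm"],
                                     lms["ad_pa_bifurcation"], pitch=0.7)
        clipped = clip_ad(mesh, lms["ad_medial"])
        line_aao = extract_centerline(clipped, lms["dao_diaphragm"],
                                      lms["aao_rpa"], pitch=0.7)
        rec = decompose_and_resample(line_ad, line_aao)
        assert rec.counts == (25, 25, 51)
        for name in ("aao", "ad", "dao"):
            truth = resample_centerline(arch.segments()[name], 600)
            d, idx = cKDTree(truth.points).query(rec.segments()[name].points)
            rel = d / truth.radius[idx]
            assert rel.mean() < 0.10, name
        tol = max(line_ad.radius.max(), line_aao.radius.max())
        assert np.linalg.norm(rec.bifurcation_origin
                              - arch.bifurcation_origin) < tol


class TestValidation:
    def test_radius_must_be_positive(self):
        with pytest.raises(ParameterError, match="radius"):
            Centerline(np.zeros((3, 3)) + np.arange(3)[:, None],
                       np.array([1.0, -1.0, 1.0])).validate()

    def test_counts_mismatch_rejected(self, clean_arch):
        _, arch = clean_arch
        with pytest.raises(SegmentError):
            arch.validate(counts=(10, 25, 51))
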