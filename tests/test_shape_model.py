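"""PCA shape model: feature assembly, oracle equivalence, reconstruction,
extreme shapes, regional RMSE and the per-mode group t-test."""

import warnings

import numpy as np
import pytest

import archssm as a
from archssm import shape_model as sm
from archssm.errors import CorrespondenceError, InsufficientDataError

# frozen hand-oracle values for the {1,2,3} vs {4,5,6} toy t-test:
# pooled sd = 1, t = -3 / sqrt(2/3), df = 4
TOY_T = -3.6742346141747673
TOY_P = 0.021311641128756713


class TestFeatures:
    def test_vector_length_404(self, aligned_cohort):
        X = sm.assemble_features(aligned_cohort[:3])
        assert X.shape == (3, 404)

    def test_assemble_disassemble_identity(self, aligned_cohort):
        arch = aligned_cohort[0]
        vec = sm.assemble_features([arch])[0]
        back = sm.disassemble_features(vec)
        for name in ("aao", "ad", "dao"):
            np.testing.assert_array_equal(back.segments()[name].points,
                                          arch.segments()[name].points)
            np.testing.assert_array_equal(back.segments()[name].radius,
                                          arch.segments()[name].radius)

    def test_identical_anatomies_identical_vectors(self, aligned_cohort):
        X = sm.assemble_features([aligned_cohort[0], aligned_cohort[0]])
        np.testing.assert_array_equal(X[0], X[1])

    def test_count_mismatch_rejected(self, aligned_cohort):
        small = a.resample_centerline(aligned_cohort[0].aao, 10)
        bad = a.ArchCenterline(small, aligned_cohort[0].ad,
                               aligned_cohort[0].dao,
                               aligned_cohort[0].bifurcation_origin)
        with pytest.raises(CorrespondenceError):
            sm.assemble_features([aligned_cohort[0], bad])


class TestFitPCA:
    def test_identical_shapes_zero_variance(self, features):
        X = np.tile(features[0], (5, 1))
        model = sm.fit_pca(X)
        np.testing.assert_allclose(model.variances, 0.0, atol=1e-18)

    def test_single_planted_direction(self):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=404)
        direction /= np.linalg.norm(direction)
        z = rng.normal(0, 4.0, size=200)
        X = 10.0 + np.outer(z, direction)
        model = sm.fit_pca(X)
        cos = abs(model.modes[0] @ direction)
        assert cos > 0.999
        assert model.variances[0] == pytest.approx(z.var(ddof=1), rel=1e-9)
        assert model.variances[1:].max() < 1e-12 * model.variances[0]

    def test_matches_covariance_eigendecomposition(self, features):
        """SVD route equals the brute-force covariance oracle (1e-8 rel)."""
        X = features[:10]
        model = sm.fit_pca(X)
        cov = np.cov(X.T, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
        m = model.n_modes
        np.testing.assert_allclose(model.variances, eigvals[:m],
                                   rtol=1e-8, atol=1e-8 * eigvals[0])
        for j in range(m):
            cos = abs(model.modes[j] @ eigvecs[:, j])
            assert cos > 1.0 - 1e-8

    def test_model_invariants(self, model, features):
        gram = model.modes @ model.modes.T
        np.testing.assert_allclose(gram, np.eye(model.n_modes), atol=1e-8)
        assert np.all(np.diff(model.variances) <= 1e-12)
        total = ((features - features.mean(0))**2).sum() / (len(features) - 1)
        assert model.variances.sum() == pytest.approx(total, rel=1e-6)
        np.testing.assert_allclose(model.coefficients.mean(axis=0), 0.0,
                                   atol=1e-8)

    def test_insufficient_cases(self, features):
        with pytest.raises(InsufficientDataError):
            sm.fit_pca(features[:1])


class TestProjectReconstruct:
    def test_mean_projects_to_zero(self, model):
        np.testing.assert_allclose(sm.project(model, model.mean), 0.0,
                                   atol=1e-9)

    def test_mode_displacement_projects_to_its_coefficient(self, model):
        vec = model.mean + 2.0 * model.modes[0]
        b = sm.project(model, vec)
        assert b[0] == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(b[1:], 0.0, atol=1e-9)

    def test_full_k_roundtrip(self, model, features):
        for i in (0, 7):
            rec = sm.reconstruct_vector(model, model.coefficients[i])
            np.testing.assert_allclose(rec, features[i], atol=1e-8)

    def test_k0_is_the_mean(self, model):
        rec = sm.reconstruct_vector(model, model.coefficients[0], k=0)
        np.testing.assert_array_equal(rec, model.mean)

    def test_radius_clamp_warns(self, model):
        # force a wildly negative radius through a huge coefficient
        coeff = np.zeros(model.n_modes)
        coeff[0] = 1e6
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            arch = sm.reconstruct(model, coeff, k=1)
        assert any("clamp" in str(w.message) for w in rec)
        assert np.all(arch.ad.radius > 0)


class TestExtremeShapes:
    def test_zero_multiple_is_the_mean(self, model):
        arch = sm.extreme_shape(model, 0, 0.0)
        vec = sm.assemble_features([arch])[0]
        np.testing.assert_allclose(vec, model.mean, atol=1e-12)

    def test_plus_minus_mirror_about_mean(self, model):
        vp = sm.assemble_features([sm.extreme_shape(model, 1, 3.0)])[0]
        vm = sm.assemble_features([sm.extreme_shape(model, 1, -3.0)])[0]
        np.testing.assert_allclose(0.5 * (vp + vm), model.mean, atol=1e-9)

    def test_planted_direction_magnitude(self):
        rng = np.random.default_rng(9)
        direction = rng.normal(size=404)
        direction /= np.linalg.norm(direction)
        z = rng.normal(0, 3.0, size=300)
        base = np.zeros(404)
        base[3::4] = 5.0  # positive radii so no clamping distorts the shape
        X = base + np.outer(z, direction)
        model = sm.fit_pca(X)
        vec = sm.assemble_features([sm.extreme_shape(model, 0, 3.0)])[0]
        moved = np.linalg.norm(vec - model.mean)
        assert moved == pytest.approx(3.0 * z.std(ddof=1), rel=0.02)


class TestReconstructionRMSE:
    def test_full_k_zero(self, model):
        assert sm.reconstruction_rmse(model, 0, model.n_modes) < 1e-8

    def test_regions_pool_correctly(self, model):
        parts = [sm.reconstruction_rmse(model, 2, 3, r)
                 for r in ("AAO", "AD", "DAO")]
        counts = model.counts
        pooled = np.sqrt(sum(c * r**2 for c, r in zip(counts, parts))
                         / sum(counts))
        assert sm.reconstruction_rmse(model, 2, 3, "ALL") == pytest.approx(
            pooled, rel=1e-9)

    def test_hand_oracle_on_toy_vectors(self):
        counts = (2, 2, 2)
        va = np.zeros(24)
        vb = np.zeros(24)
        # displace point 0 by (3,4,0) -> distance 5; point 5 by (0,0,2)
        vb[0], vb[1] = 3.0, 4.0
        vb[20 + 2] = 2.0
        rmse = sm.feature_point_rmse(va, vb, counts, "ALL")
        assert rmse == pytest.approx(np.sqrt((25.0 + 4.0) / 6.0))
        assert sm.feature_point_rmse(va, vb, counts, "AAO") == pytest.approx(
            np.sqrt(25.0 / 2.0))

    def test_full_vector_error_monotone_in_k(self, model, features):
        """The complete feature-vector error shrinks with every mode."""
        for case in (0, 5, 11):
            errs = [np.linalg.norm(
                sm.reconstruct_vector(model, model.coefficients[case], k)
                - features[case]) for k in range(0, model.n_modes + 1, 7)]
            assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_cohort_mean_region_curves_monotone(self, model):
        ks = range(0, model.n_modes + 1, 11)
        for region in ("ALL", "AAO", "NEAR_BIFURCATION"):
            curve = [np.mean([sm.reconstruction_rmse(model, c, k, region)
                              for c in range(model.n_cases)]) for k in ks]
            assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(curve, curve[1:]))

    def test_near_bifurcation_point_counts(self):
        idx = sm.region_point_indices("NEAR_BIFURCATION", (25, 25, 51))
        assert len(idx) == 13 + 13 + 26


class TestModeGroupTTest:
    def test_toy_oracle(self):
        # one mode whose coefficients are {1,2,3} vs {4,5,6}
        model = sm.ShapeModel(
            mean=np.zeros(404), modes=np.eye(1, 404),
            variances=np.array([1.0]),
            coefficients=np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]))
        out = sm.mode_group_ttest(model, np.array([0, 0, 0, 1, 1, 1]))
        assert out["t"].iloc[0] == pytest.approx(TOY_T, abs=1e-9)
        assert out["p"].iloc[0] == pytest.approx(TOY_P, abs=1e-9)
        assert not out["significant"].iloc[0]

    def test_identical_distributions(self):
        coeffs = np.array([[1.0], [2.0], [1.0], [2.0]])
        model = sm.ShapeModel(mean=np.zeros(404), modes=np.eye(1, 404),
                              variances=np.array([1.0]), coefficients=coeffs)
        out = sm.mode_group_ttest(model, np.array([0, 0, 1, 1]))
        assert out["t"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_shift_detected_null_rate_calibrated(self):
        """A 2 SD shift on mode 1 only flags it; null modes flag at ~1%."""
        rng = np.random.default_rng(77)
        n, m = 200, 50
        hits = 0
        null_flags, null_total = 0, 0
        for _ in range(40):
            labels = np.zeros(n, dtype=int)
            labels[:n // 2] = 1
            rng.shuffle(labels)
            coeffs = rng.normal(size=(n, m))
            coeffs[labels == 1, 0] += 2.0  # 2 SD shift on mode 1 only
            coeffs -= coeffs.mean(axis=0)
            model = sm.ShapeModel(mean=np.zeros(404),
                                  modes=np.eye(m, 404),
                                  variances=coeffs.var(axis=0, ddof=1),
                                  coefficients=coeffs)
            out = sm.mode_group_ttest(model, labels)
            hits += bool(out["significant"].iloc[0])
            null_flags += int(out["significant"].iloc[1:].sum())
            null_total += m - 1
        assert hits == 40
        rate = null_flags / null_total
        assert 0.003 < rate < 0.025

    def test_single_class_error(self, model):
        with pytest.raises(InsufficientDataError):
            sm.mode_group_ttest(model, np.zeros(model.n_cases, dtype=int))


def test_serialization_roundtrip(tmp_path, model):
    path = tmp_path / "model.npz"
    sm.save_model(model, path)
    back = sm.load_model(path)
    np.testing.assert_array_equal(back.mean, model.mean)
    np.testing.assert_array_equal(back.modes, model.modes)
    np.testing.assert_array_equal(back.variances, model.variances)
    np.testing.assert_array_equal(back.coefficients, model.coefficients)
    assert back.case_ids == model.case_ids
    assert back.counts == model.counts
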