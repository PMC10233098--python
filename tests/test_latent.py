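import numpy as np
import pytest
from scipy.stats import multivariate_normal

from kinvae import (
    FEATURE_NAMES,
    FeatureDataset,
    PerturbationTrace,
    assignment_posterior,
    feature_density_map,
    fit_class_gaussian,
    fit_class_gaussians,
    latent_alignment,
    pca_explained_variance,
    perturb_feature,
    project_latent,
)
from kinvae.exceptions import FeatureNameError, PairingError
from kinvae.latent import VARIANCE_FLOOR, assignment_posteriors


class TestProjectLatent:
    def test_one_point_per_participant(self, small_results, small_table):
        proj = project_latent(small_results, small_table)
        n_participants = small_table.frame.participant_id.nunique()
        assert len(proj.participant_points) == n_participants
        assert proj.latent_dim == 2

    def test_participant_point_is_mean_of_task_points(self, small_results, small_table):
        proj = project_latent(small_results, small_table)
        pid = proj.participant_points.participant_id.iloc[0]
        task_mu = proj.task_points[proj.task_points.participant_id == pid][["z0", "z1"]]
        want = task_mu.mean(axis=0).to_numpy()
        got = proj.participant_points.iloc[0][["z0", "z1"]].to_numpy(dtype=float)
        assert got == pytest.approx(want, abs=1e-12)

    def test_deterministic(self, small_results, small_table):
        a = project_latent(small_results, small_table)
        b = project_latent(small_results, small_table)
        assert np.array_equal(a.task_array(), b.task_array())


class TestPCA:
    def test_planar_points_in_10d_have_rank2_spectrum(self):
        rng = np.random.default_rng(0)
        basis = np.linalg.qr(rng.normal(size=(10, 2)))[0]
        pts = rng.normal(size=(200, 2)) @ basis.T
        res = pca_explained_variance(pts)
        assert res.cumulative()[1] == pytest.approx(1.0, abs=1e-9)
        assert res.n_components_for(0.95) == 2

    def test_isotropic_gaussian_has_flat_spectrum(self):
        pts = np.random.default_rng(1).normal(size=(10_000, 10))
        res = pca_explained_variance(pts)
        assert np.all(np.abs(res.explained_variance_ratios - 0.1) < 0.02)

    def test_ratios_nonincreasing_and_sum_to_one(self):
        pts = np.random.default_rng(2).normal(size=(50, 6)) * np.arange(1, 7)
        r = pca_explained_variance(pts).explained_variance_ratios
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() == pytest.approx(1.0, abs=1e-9)


class TestClassGaussian:
    def test_two_point_fit_hand_computed(self):
        g = fit_class_gaussian(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert g.mean == pytest.approx([1.0, 1.0])
        assert g.variances == pytest.approx([1.0, 1.0])  # MLE divide-by-n

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        true_mean, true_var = np.array([1.0, -2.0]), np.array([0.5, 2.0])
        pts = rng.normal(true_mean, np.sqrt(true_var), size=(10_000, 2))
        g = fit_class_gaussian(pts)
        se_mean = np.sqrt(true_var / 10_000)
        assert np.all(np.abs(g.mean - true_mean) < 3 * se_mean)
        se_var = true_var * np.sqrt(2 / 10_000)
        assert np.all(np.abs(g.variances - true_var) < 3 * se_var)

    def test_identical_points_hit_variance_floor(self):
        g = fit_class_gaussian(np.ones((5, 2)))
        assert g.variances == pytest.approx([VARIANCE_FLOOR] * 2)


class TestAssignmentPosterior:
    def _gaussians(self):
        g0 = fit_class_gaussian(np.array([[-1.0, 0.0], [-3.0, 2.0], [-2.0, -2.0]]), 0)
        g1 = fit_class_gaussian(np.array([[1.0, 0.0], [3.0, 2.0], [2.0, -2.0]]), 1)
        return g0, g1

    def test_symmetric_point_is_fifty_fifty(self):
        g0, g1 = self._gaussians()
        p_td, p_asd = assignment_posterior(np.array([0.0, 0.0]), g0, g1)
        assert p_td == pytest.approx(0.5)
        assert p_asd == pytest.approx(0.5)

    def test_point_far_inside_one_class(self):
        g0, g1 = self._gaussians()
        far = g0.mean + np.array([-100.0 * np.sqrt(g0.variances[0]), 0.0])
        p_td, _ = assignment_posterior(far, g0, g1)
        assert p_td >= 1 - 1e-10

    def test_matches_direct_density_evaluation(self):
        g0, g1 = self._gaussians()
        pt = np.array([0.3, -0.7])
        d0 = multivariate_normal(g0.mean, np.diag(g0.variances)).pdf(pt)
        d1 = multivariate_normal(g1.mean, np.diag(g1.variances)).pdf(pt)
        p_td, p_asd = assignment_posterior(pt, g0, g1)
        assert p_td == pytest.approx(d0 / (d0 + d1), rel=1e-12)
        assert p_asd == pytest.approx(d1 / (d0 + d1), rel=1e-12)

    def test_posteriors_finite_and_normalized_under_extremes(self):
        g0, g1 = self._gaussians()
        pts = np.array([[1e3, -1e3], [0.0, 0.0], [-1e3, 1e3]])
        post = assignment_posteriors(pts, g0, g1)
        assert np.all(np.isfinite(post))
        assert np.allclose(post.sum(axis=1), 1.0)


class TestPerturbFeature:
    def test_trace_has_n_positions(self, small_results, small_table):
        pid = small_table.frame.participant_id.iloc[0]
        trace = perturb_feature(small_results, small_table, pid, "MaxSpeed",
                                n=17, seed=0)
        assert trace.n == 17
        assert trace.latent_positions.shape == (17, 2)
        assert np.allclose(trace.posterior_per_sample.sum(axis=1), 1.0)

    def test_zero_sd_feature_gives_identical_positions(self, small_results, small_table):
        frame = small_table.frame.copy()
        frame["STH"] = 0.9
        ds = FeatureDataset(frame)
        pid = frame.participant_id.iloc[0]
        trace = perturb_feature(small_results, ds, pid, "STH", n=10, seed=0)
        assert np.allclose(trace.latent_positions, trace.latent_positions[0])

    def test_unknown_feature_rejected(self, small_results, small_table):
        with pytest.raises(FeatureNameError):
            perturb_feature(small_results, small_table,
                            small_table.frame.participant_id.iloc[0], "Wiggliness")

    def test_seeded_reproducibility(self, small_results, small_table):
        pid = small_table.frame.participant_id.iloc[0]
        a = perturb_feature(small_results, small_table, pid, "sdSpeed", n=8, seed=5)
        b = perturb_feature(small_results, small_table, pid, "sdSpeed", n=8, seed=5)
        assert np.array_equal(a.latent_positions, b.latent_positions)


class TestDensityMap:
    def _trace(self, pts):
        pts = np.asarray(pts, dtype=float)
        return PerturbationTrace("P0", "MaxSpeed", np.zeros(len(pts)), pts,
                                 np.full((len(pts), 2), 0.5), pts[0])

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        traces = [self._trace(rng.normal(size=(100, 2))) for _ in range(3)]
        H, xe, ye = feature_density_map(traces, bins=25)
        area = (xe[1] - xe[0]) * (ye[1] - ye[0])
        assert H.sum() * area == pytest.approx(1.0, abs=1e-6)

    def test_repeated_position_concentrates_in_one_cell(self):
        traces = [self._trace(np.tile([0.5, 0.5], (50, 1)))]
        H, xe, ye = feature_density_map(traces, bins=10,
                                        extent=(0, 1, 0, 1))
        area = (xe[1] - xe[0]) * (ye[1] - ye[0])
        assert (H > 0).sum() == 1
        assert H.max() * area == pytest.approx(1.0)

    def test_mode_near_mean_for_unimodal_cloud(self):
        rng = np.random.default_rng(4)
        pts = rng.normal([1.0, -1.0], 0.3, size=(5000, 2))
        H, xe, ye = feature_density_map([self._trace(pts)], bins=30)
        i, j = np.unravel_index(H.argmax(), H.shape)
        mode = [(xe[i] + xe[i + 1]) / 2, (ye[j] + ye[j + 1]) / 2]
        assert mode == pytest.approx(pts.mean(axis=0), abs=0.3)


class TestLatentAlignment:
    def test_pure_rotation_recovered_exactly(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(40, 2))
        R = np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degrees
        comp = ref @ R.T
        al = latent_alignment(ref, comp)
        assert al.residual_rms == pytest.approx(0.0, abs=1e-10)
        assert al.rotation @ R.T == pytest.approx(np.eye(2), abs=1e-10)

    def test_self_alignment_is_identity(self):
        pts = np.random.default_rng(1).normal(size=(30, 3))
        al = latent_alignment(pts, pts)
        assert al.rotation == pytest.approx(np.eye(3), abs=1e-10)
        assert al.relative_residual == pytest.approx(0.0, abs=1e-10)

    def test_noise_level_reflected_in_residual(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(200, 2))
        comp = ref + rng.normal(scale=0.05, size=ref.shape)
        al = latent_alignment(ref, comp)
        assert 0.02 < al.residual_rms < 0.12

    def test_mismatched_sets_rejected(self):
        with pytest.raises(PairingError):
            latent_alignment(np.zeros((5, 2)), np.zeros((6, 2)))


def test_decision_rules_agree_on_training_cohort(small_results, small_table):
    """Gaussian-posterior classification and the predictor head estimate the
    same separation: their arg-max decisions agree on participant points."""
    from kinvae import nn

    proj = project_latent(small_results, small_table)
    g_td, g_asd = fit_class_gaussians(proj)
    pts = proj.participant_array()
    post_rule = assignment_posteriors(pts, g_td, g_asd).argmax(axis=1)
    pred_rule = nn.predict_proba_from_latent(
        small_results.trained.params, pts, small_results.config).argmax(axis=1)
    assert np.mean(post_rule == pred_rule) >= 0.9


def test_class_gaussians_separate_on_synthetic_cohort(small_results, small_table):
    proj = project_latent(small_results, small_table)
    g_td, g_asd = fit_class_gaussians(proj)
    pooled = np.sqrt((g_td.variances + g_asd.variances) / 2)
    distance = np.linalg.norm((g_td.mean - g_asd.mean) / pooled)
    assert distance >= 2.0
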