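"""BLME trajectory model: REML recovery, conjugacy oracles, erf maps."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from helpers import block_gls, grid_posterior_moments

from atrophy_forecast import blme
from atrophy_forecast.blme import (
    ClusterVolumeResult,
    DeviationMap,
    PosteriorPrediction,
    cluster_volume,
    deviation_map,
    erf_score,
    fit_control_model,
    fit_subject_posterior,
    posterior_update,
    predict,
)
from atrophy_forecast.cohort import CohortConfig, simulate_cohort
from atrophy_forecast.exceptions import (
    DegeneratePredictionError,
    EligibilityError,
    FitError,
    ProtocolError,
)


class TestControlModelFit:
    def test_noise_free_shared_slope_recovered_exactly(self):
        cfg = CohortConfig(
            n_controls=5, n_carriers=0, grid_shape=(6, 6, 6), seed=8,
            baseline_volume_sd=0.0, control_slope_sd=0.0,
            residual_noise_sd=0.0, control_slope_mean=-0.5,
            baseline_volume_mean=10.0)
        model = fit_control_model(simulate_cohort(cfg))
        # spatial intercept varies per voxel but the slope is global
        np.testing.assert_allclose(model.beta[1], -0.5, rtol=0, atol=1e-9)
        assert np.all(model.sigma2_at() <= 1e-12)

    def test_reml_variance_recovery(self):
        """REML components within 25% of the generating values."""
        cfg = CohortConfig(
            n_controls=50, n_carriers=0, grid_shape=(6, 6, 6), seed=17,
            n_scans_per_subject=4, baseline_volume_mean=50.0,
            baseline_volume_sd=0.6, control_slope_mean=-0.5,
            control_slope_sd=0.2, residual_noise_sd=1.0)
        model = fit_control_model(simulate_cohort(cfg), mode="pooled")
        assert model.sigma_b[0, 0] == pytest.approx(0.6 ** 2, rel=0.25)
        assert model.sigma_b[1, 1] == pytest.approx(0.2 ** 2, rel=0.25)
        assert float(np.mean(model.sigma2_at())) == pytest.approx(1.0, rel=0.25)

    def test_fixed_effects_match_explicit_gls(self, rng):
        """Single voxel, 10 observations: closed form vs stacked-matrix GLS."""
        sigma_b = np.array([[0.4, 0.05], [0.05, 0.1]])
        sigma2 = 0.3
        times = [np.array([0.0, 1.0]), np.array([0.0, 1.5, 3.0]),
                 np.array([0.0, 2.0]), np.array([0.0, 1.0, 2.0])]
        ys = [rng.normal(size=len(t)) for t in times]

        t_all = np.concatenate(times)
        groups = np.concatenate([np.full(len(t), i)
                                 for i, t in enumerate(times)])
        Y = np.concatenate(ys)[:, None]
        ours = blme._gls_fixed_effects(Y, t_all, groups, sigma_b, sigma2)[:, 0]
        oracle = block_gls(times, ys, sigma_b, sigma2)
        np.testing.assert_allclose(ours, oracle, rtol=1e-10)

    def test_too_few_controls_rejected(self, small_cohort):
        thin = dataclasses.replace(small_cohort,
                                   subjects=small_cohort.carriers)
        with pytest.raises(FitError):
            fit_control_model(thin)

    def test_voxel_mode_gives_per_voxel_components(self):
        cfg = CohortConfig(n_controls=10, n_carriers=0, grid_shape=(3, 3, 3),
                           acceleration_cluster_radius_voxels=1.0, seed=6)
        model = fit_control_model(simulate_cohort(cfg), mode="voxel")
        assert model.sigma_b.shape == (27, 2, 2)
        assert model.sigma2_at().shape == (27,)
        assert np.all(model.sigma2_at() > 0)


class TestPosteriorConjugacy:
    def test_posterior_matches_grid_integration(self, rng):
        """Closed-form conjugate update vs 2D brute-force integration."""
        beta = np.array([1.0, -0.4])
        sigma_b = np.array([[0.25, 0.03], [0.03, 0.04]])
        sigma2 = 0.09
        times = np.array([0.0, 1.2])
        y = np.array([1.3, 0.4])

        mean, cov = posterior_update(times, y[:, None], beta[:, None],
                                     sigma_b, sigma2)
        g_mean, g_cov, g_pred, g_sd = grid_posterior_moments(
            times, y, beta, sigma_b, sigma2, t_query=3.0)
        np.testing.assert_allclose(mean[:, 0], g_mean, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(cov, g_cov, rtol=1e-4, atol=1e-6)

        # and the posterior predictive at a later time
        model = blme.ControlModel(
            beta=beta[:, None], sigma_b=sigma_b, sigma2_eps=sigma2,
            mask=np.ones((1, 1, 1), bool), n_controls=1, n_scans=2)
        post = blme.SubjectPosterior(subject_id="x", mean=mean, cov=cov,
                                     pair_times=(0.0, 1.2))
        pred = predict(post, model, 3.0)
        assert pred.mean[0] == pytest.approx(g_pred, rel=1e-4)
        assert pred.sd[0] == pytest.approx(g_sd, rel=1e-4)

    def test_five_observation_instance_matches_grid(self, rng):
        beta = np.array([0.5, -0.2])
        sigma_b = np.array([[0.09, -0.01], [-0.01, 0.02]])
        sigma2 = 0.04
        times = np.array([0.0, 0.8, 1.7, 2.5, 3.1])
        y = beta[0] + beta[1] * times + rng.normal(0, 0.3, size=5)

        mean, cov = posterior_update(times, y[:, None], beta[:, None],
                                     sigma_b, sigma2)
        g_mean, g_cov = grid_posterior_moments(times, y, beta, sigma_b, sigma2)
        np.testing.assert_allclose(mean[:, 0], g_mean, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(cov, g_cov, rtol=1e-4, atol=1e-6)

    def test_degenerate_prior_pins_subject_to_population(self):
        """Zero random-effect covariance leaves no room to deviate."""
        beta = np.array([[2.0], [-0.3]])
        mean, cov = posterior_update(np.array([0.0, 1.0]),
                                     np.array([[5.0], [9.0]]),
                                     beta, np.zeros((2, 2)), 0.5)
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(cov, 0.0, atol=1e-12)

    def test_zero_noise_posterior_interpolates(self):
        """With no residual noise the posterior line passes through the data."""
        beta = np.array([[1.0], [0.0]])
        sigma_b = np.array([[0.5, 0.0], [0.0, 0.5]])
        times = np.array([0.0, 2.0])
        y = np.array([[2.0], [3.0]])
        mean, cov = posterior_update(times, y, beta, sigma_b, 0.0)
        line = beta[:, 0] + mean[:, 0]
        np.testing.assert_allclose(line[0] + line[1] * times, y[:, 0],
                                   atol=1e-9)
        # posterior variance never exceeds the prior, component-wise
        assert cov[0, 0] <= sigma_b[0, 0] + 1e-12
        assert cov[1, 1] <= sigma_b[1, 1] + 1e-12

    def test_eligibility_enforced(self, small_cohort, small_control_model):
        subj = next(s for s in small_cohort.carriers if len(s.scans) >= 3)
        bad = dataclasses.replace(subj, scans=[
            dataclasses.replace(subj.scans[0], cdr_global=1.0),
            *subj.scans[1:]])
        with pytest.raises(EligibilityError, match="CDR"):
            fit_subject_posterior(small_cohort, bad, small_control_model)


class TestPrediction:
    def _toy_model_and_posterior(self):
        model = blme.ControlModel(
            beta=np.array([[1.0], [-0.2]]),
            sigma_b=np.array([[0.1, 0.0], [0.0, 0.05]]), sigma2_eps=0.04,
            mask=np.ones((1, 1, 1), bool), n_controls=5, n_scans=10)
        post = blme.SubjectPosterior(
            subject_id="s", mean=np.array([[0.1], [-0.05]]),
            cov=np.array([[0.02, 0.001], [0.001, 0.01]]),
            pair_times=(0.0, 1.0))
        return model, post

    def test_mean_is_linear_in_time(self):
        model, post = self._toy_model_and_posterior()
        p0, p1, p2 = (predict(post, model, t) for t in (0.0, 1.0, 2.0))
        assert p2.mean[0] - p1.mean[0] == pytest.approx(
            p1.mean[0] - p0.mean[0], rel=1e-12)

    def test_predictive_sd_grows_away_from_pair_center(self):
        model, post = self._toy_model_and_posterior()
        sds = [predict(post, model, t).sd[0] for t in (1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(sds) > 0)
        # variance is a quadratic in t: its minimum sits at the center of
        # information, so any t past the pair is above the minimum
        t_min = -post.cov[0, 1] / post.cov[1, 1]
        assert predict(post, model, max(t_min, 0.0)).sd[0] <= sds[0] + 1e-12


class TestErfScore:
    def _unit_prediction(self):
        return PosteriorPrediction(t=1.0, mean=np.array([0.0]),
                                   sd=np.array([1.0]))

    def test_zero_at_predicted_value(self):
        assert erf_score(np.array([0.0]), self._unit_prediction())[0] == 0.0

    def test_one_sd_matches_normal_integral(self):
        """erf at -1 SD equals the central normal mass on [-1, 1], negated."""
        val = erf_score(np.array([-1.0]), self._unit_prediction())[0]
        mass, _ = integrate.quad(stats.norm.pdf, -1, 1)
        assert val == pytest.approx(-mass, abs=1e-3)
        assert val == pytest.approx(-0.6827, abs=1e-3)

    def test_tail_probability_at_map_threshold(self):
        """|erf| = 0.999 corresponds to a two-sided tail probability 0.001."""
        z = np.sqrt(2.0) * stats.norm.ppf(1 - 0.001 / 2) / np.sqrt(2.0)
        # observed value whose standardized deviation has two-sided tail 0.001
        obs = np.array([-stats.norm.ppf(1 - 0.001 / 2)])
        score = erf_score(obs, self._unit_prediction())[0]
        assert 1 - abs(score) == pytest.approx(0.001, rel=1e-9)

    def test_degenerate_sd_rejected(self):
        pred = PosteriorPrediction(t=1.0, mean=np.array([0.0]),
                                   sd=np.array([0.0]))
        with pytest.raises(DegeneratePredictionError):
            erf_score(np.array([1.0]), pred)


class TestDeviationMaps:
    def test_noiseless_subject_scores_zero(self, noise_free_cohort):
        model = fit_control_model(noise_free_cohort)
        # inject a tiny artificial residual variance so scoring is defined
        model = blme.ControlModel(beta=model.beta, sigma_b=model.sigma_b,
                                  sigma2_eps=1e-6, mask=model.mask,
                                  n_controls=model.n_controls,
                                  n_scans=model.n_scans)
        subj = noise_free_cohort.carriers[0]
        post = fit_subject_posterior(noise_free_cohort, subj, model)
        dmap = deviation_map(noise_free_cohort, subj, 2, post, model)
        np.testing.assert_allclose(dmap.values[dmap.mask], 0.0, atol=1e-6)

    def test_predictor_pair_never_scored(self, small_cohort,
                                         small_control_model):
        subj = small_cohort.carriers[0]
        post = fit_subject_posterior(small_cohort, subj, small_control_model)
        with pytest.raises(ProtocolError):
            deviation_map(small_cohort, subj, 1, post, small_control_model)

    def test_injected_deficit_detected(self, small_cohort,
                                       small_control_model):
        """A 5-predictive-SD deficit in a 10-voxel ball crosses -0.999."""
        cohort = small_cohort
        model = small_control_model
        subj = next(s for s in cohort.carriers
                    if not s.truth["accelerates"])
        post = fit_subject_posterior(cohort, subj, model)
        scan = subj.scans[2]
        pred = predict(post, model, scan.scan_time_years)

        key = (subj.subject_id, scan.scan_index)
        img = cohort.images[key]
        ball = np.zeros(cohort.mask.shape, bool)
        ball[3:5, 3:5, 3:5] = True  # 8 voxels
        flat_ball = ball[cohort.mask]
        doctored = img.values.copy()
        doctored[cohort.mask] = np.where(
            flat_ball, pred.mean - 5 * pred.sd, img.values[cohort.mask])
        cohort.images[key] = dataclasses.replace(img, values=doctored)
        try:
            dmap = deviation_map(cohort, subj, scan.scan_index, post, model)
        finally:
            cohort.images[key] = img

        assert np.all(dmap.values[ball] < -0.999)
        outside = dmap.values[cohort.mask & ~ball]
        assert np.mean(np.abs(outside) > 0.999) < 0.01
        assert np.nanmax(np.abs(dmap.values[dmap.mask])) <= 1.0


class TestClusterVolume:
    def _map_from(self, values):
        arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        return DeviationMap(values=arr, mask=np.ones_like(arr, bool),
                            subject_id="s", scan_index=2, t=2.0)

    def test_all_zero_map_has_zero_volume(self):
        dmap = self._map_from(np.zeros(20))
        for thr in blme.DEFAULT_ERF_THRESHOLDS:
            assert cluster_volume(dmap, thr, 8.0).volume_mm3 == 0.0

    def test_volume_arithmetic(self):
        dmap = self._map_from([-0.9995] * 5 + [0.0] * 7)
        res = cluster_volume(dmap, -0.999, 8.0)
        assert res.n_voxels == 5
        assert res.volume_mm3 == 40.0

    def test_threshold_monotonicity(self, rng):
        vals = np.clip(rng.normal(0, 0.6, size=200), -0.99999, 0.99999)
        dmap = self._map_from(vals)
        volumes = [cluster_volume(dmap, thr, 8.0).volume_mm3
                   for thr in sorted(blme.DEFAULT_ERF_THRESHOLDS)]
        # thresholds sorted ascending (most stringent first): non-decreasing
        assert np.all(np.diff(volumes) >= 0)

    def test_threshold_domain_enforced(self):
        dmap = self._map_from(np.zeros(3))
        for bad in (-1.0, 0.0, 0.5, -2.0):
            with pytest.raises(ValueError):
                cluster_volume(dmap, bad, 8.0)


class TestSlopeRecovery:
    def test_posterior_slopes_track_truth(self):
        """Posterior slope means correlate with simulated subject slopes."""
        cfg = CohortConfig(
            n_controls=50, n_carriers=200, grid_shape=(6, 6, 6), seed=77,
            control_slope_sd=0.04, residual_noise_sd=0.02,
            acceleration_magnitude=0.0, prop_converters=0.0,
            acceleration_cluster_radius_voxels=2.0)
        cohort = simulate_cohort(cfg)
        model = fit_control_model(cohort)
        est, truth = [], []
        for subj in cohort.carriers:
            post = fit_subject_posterior(cohort, subj, model)
            est.append(float(post.mean[1].mean()))
            truth.append(subj.truth["slope_offset"])
        r = np.corrcoef(est, truth)[0, 1]
        assert r > 0.7
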