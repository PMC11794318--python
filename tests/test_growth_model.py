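import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapnet import (
    MCMCConfig,
    PosteriorSamples,
    SimScenario,
    SiteRegistry,
    exp_correlation,
    fit_growth_model,
    generate_dataset,
    krige_params,
    logistic_mean,
    predict_cumulative,
)
from trapnet.growth_model import PredictionResult


class TestLogisticMean:
    def test_midpoint_is_half_asymptote(self):
        assert logistic_mean(5.0, 10.0, 5.0, 1.3) == pytest.approx(5.0)

    def test_limits(self):
        assert logistic_mean(-1e4, 10.0, 5.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert logistic_mean(1e4, 10.0, 5.0, 1.0) == pytest.approx(10.0)

    def test_point_value(self):
        assert logistic_mean(6.0, 10.0, 5.0, 1.0) == pytest.approx(
            10.0 / (1.0 + math.exp(-1.0))
        )

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            logistic_mean(1.0, 10.0, 5.0, 0.0)
        with pytest.raises(ValueError):
            logistic_mean(1.0, 10.0, 5.0, -1.0)

    @given(
        beta=st.floats(0.1, 1e3),
        gamma=st.floats(-5, 15),
        k=st.floats(0.1, 10),
        offset=st.floats(-15, 15),
        delta=st.floats(0.01, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_week(self, beta, gamma, k, offset, delta):
        # stay within the numerically meaningful band around the midpoint
        w1 = gamma + k * offset
        w2 = w1 + k * delta
        assert logistic_mean(w2, beta, gamma, k) > logistic_mean(w1, beta, gamma, k)

    def test_increasing_in_beta(self):
        assert logistic_mean(4.0, 20.0, 5.0, 1.0) > logistic_mean(4.0, 10.0, 5.0, 1.0)


class TestExpCorrelation:
    def test_unit_diagonal(self, tri_registry):
        C = exp_correlation(tri_registry, rho=2.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_one_km_pair(self):
        reg = SiteRegistry((1, 2), np.array([[0.0, 0.0], [1.0, 0.0]]))
        C = exp_correlation(reg, rho=1.0)
        assert C[0, 1] == pytest.approx(math.exp(-1.0))

    def test_limits(self, tri_registry):
        near_one = exp_correlation(tri_registry, rho=1e9)
        assert np.all(near_one > 0.999)
        far = SiteRegistry((1, 2), np.array([[0.0, 0.0], [1e6, 0.0]]))
        assert exp_correlation(far, rho=1.0)[0, 1] == pytest.approx(0.0, abs=1e-300)

    def test_nonpositive_rho_rejected(self, tri_registry):
        with pytest.raises(ValueError):
            exp_correlation(tri_registry, rho=0.0)

    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12), rho=st.floats(0.1, 50))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_psd_unit_diagonal(self, seed, n, rho):
        rng = np.random.default_rng(seed)
        reg = SiteRegistry(tuple(range(1, n + 1)), rng.random((n, 2)) * 20)
        C = exp_correlation(reg, rho=rho)
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.all((C > 0) & (C <= 1.0))
        eigs = np.linalg.eigvalsh(C)
        assert eigs.min() > -1e-8


def _single_draw_posterior(registry, beta, gamma, k=1.0, mu_beta=0.0, mu_gamma=0.0,
                           rho_beta=1.0, rho_gamma=1.0, n_draws=1):
    shape = (n_draws, len(registry.site_ids))
    return PosteriorSamples(
        train_registry=registry,
        beta=np.broadcast_to(np.asarray(beta, float), shape).copy(),
        gamma=np.broadcast_to(np.asarray(gamma, float), shape).copy(),
        k=np.full(n_draws, k),
        sigma2=np.full(n_draws, 0.1),
        mu_beta=np.full(n_draws, mu_beta),
        mu_gamma=np.full(n_draws, mu_gamma),
        sigma2_beta=np.full(n_draws, 1.0),
        sigma2_gamma=np.full(n_draws, 1.0),
        rho_beta=np.full(n_draws, rho_beta),
        rho_gamma=np.full(n_draws, rho_gamma),
    )


class TestKrigeParams:
    def test_far_target_reverts_to_process_mean(self):
        reg = SiteRegistry((1, 2), np.array([[0.0, 0.0], [1.0, 0.0]]))
        post = _single_draw_posterior(reg, [5.0, 7.0], [4.0, 6.0], mu_beta=3.0, mu_gamma=2.0)
        targets = SiteRegistry((90, 91), np.array([[1e5, 1e5], [2e5, 2e5]]))
        beta_star, gamma_star = krige_params(post, targets)
        np.testing.assert_allclose(beta_star, 3.0, atol=1e-6)
        np.testing.assert_allclose(gamma_star, 2.0, atol=1e-6)

    def test_coincident_target_is_exact(self):
        reg = SiteRegistry((1, 2), np.array([[0.0, 0.0], [3.0, 4.0]]))
        post = _single_draw_posterior(reg, [5.0, 7.0], [4.0, 6.0])
        targets = SiteRegistry((90, 91), np.array([[3.0, 4.0], [10.0, 0.0]]))
        beta_star, gamma_star = krige_params(post, targets)
        assert beta_star[0, 0] == pytest.approx(7.0)
        assert gamma_star[0, 0] == pytest.approx(6.0)

    def test_scalar_closed_form(self):
        # single training site: simple kriging collapses to r * beta
        reg = SiteRegistry((1,), np.array([[0.0, 0.0]]))
        post = _single_draw_posterior(reg, [2.0], [0.0], rho_beta=1.0)
        targets = SiteRegistry((90,), np.array([[1.0, 0.0]]))
        beta_star, _ = krige_params(post, targets)
        assert beta_star[0, 0] == pytest.approx(2.0 * math.exp(-1.0), rel=1e-6)

    def test_empty_posterior_rejected(self):
        reg = SiteRegistry((1, 2), np.array([[0.0, 0.0], [1.0, 0.0]]))
        post = _single_draw_posterior(reg, [1.0, 1.0], [1.0, 1.0])
        post.k = np.empty(0)
        with pytest.raises(ValueError, match="empty"):
            krige_params(post, reg)


class TestPredictCumulative:
    def test_single_draw_equals_logistic(self):
        reg = SiteRegistry((1, 2), np.array([[0.0, 0.0], [1e6, 1e6]]))
        post = _single_draw_posterior(reg, [8.0, 8.0], [5.0, 5.0], k=1.5)
        pred = predict_cumulative(post, reg, weeks=range(1, 8))
        expected = logistic_mean(np.arange(1, 8), 8.0, 5.0, 1.5)
        np.testing.assert_allclose(pred.mean[0], expected, rtol=1e-10)

    def test_two_draw_mean_at_midpoint(self):
        reg = SiteRegistry((1, 2), np.array([[0.0, 0.0], [1.0, 0.0]]))
        post = _single_draw_posterior(reg, [10.0, 10.0], [4.0, 4.0], k=1.0, n_draws=2)
        post.beta[1] = 20.0
        pred = predict_cumulative(post, reg, weeks=[4])
        # mean of beta/2 over draws: (5 + 10) / 2
        assert pred.mean[0, 0] == pytest.approx(7.5)

    def test_empty_weeks_rejected(self):
        reg = SiteRegistry((1, 2), np.array([[0.0, 0.0], [1.0, 0.0]]))
        post = _single_draw_posterior(reg, [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="week"):
            predict_cumulative(post, reg, weeks=[])

    def test_rigid_motion_and_reordering_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.random((4, 2)) * 10
        reg = SiteRegistry((1, 2, 3, 4), coords)
        beta = rng.random(4) * 10
        gamma = rng.random(4) * 3 + 3
        post = _single_draw_posterior(reg, beta, gamma, rho_beta=5.0, rho_gamma=5.0)
        target = SiteRegistry((90, 91), rng.random((2, 2)) * 10)
        base, _ = krige_params(post, target)

        # rotate + translate everything rigidly
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([100.0, -50.0])
        reg2 = SiteRegistry((1, 2, 3, 4), coords @ R.T + shift)
        post2 = _single_draw_posterior(reg2, beta, gamma, rho_beta=5.0, rho_gamma=5.0)
        target2 = SiteRegistry((90, 91), target.coords @ R.T + shift)
        moved, _ = krige_params(post2, target2)
        np.testing.assert_allclose(moved, base, rtol=1e-9)

        # permute training site order
        perm = [2, 0, 3, 1]
        reg3 = SiteRegistry((3, 1, 4, 2), coords[perm])
        post3 = _single_draw_posterior(reg3, beta[perm], gamma[perm],
                                       rho_beta=5.0, rho_gamma=5.0)
        permuted, _ = krige_params(post3, target)
        np.testing.assert_allclose(permuted, base, rtol=1e-9)


class TestFitGrowthModel:
    def test_single_site_rejected(self, small_dataset, fast_mcmc):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="2 training sites"):
            fit_growth_model(ds, [1], [2021], fast_mcmc)

    def test_parameter_recovery_low_noise(self):
        scenario = SimScenario(
            L=10,
            region_km=(20.0, 20.0),
            weeks_per_year={2021: 10, 2022: 11},
            absent_site_years=frozenset(),
            missing_site_weeks=frozenset(),
            sigma2=1e-4,
            seed=21,
        )
        ds, truth = generate_dataset(scenario)
        post = fit_growth_model(
            ds, ds.registry.site_ids, ds.years, MCMCConfig(chains=2, warmup=400,
                                                           draws=400, seed=5)
        )
        beta_hat = post.beta.mean(axis=0)
        gamma_hat = post.gamma.mean(axis=0)
        np.testing.assert_allclose(beta_hat, truth["params"]["beta"], rtol=0.05)
        np.testing.assert_allclose(gamma_hat, truth["params"]["gamma"], rtol=0.05)
        assert post.k.mean() == pytest.approx(truth["params"]["k"], rel=0.05)

    def test_k_interval_coverage(self):
        # raw Normal cumulative draws so generator and likelihood agree
        # exactly (the monotone projection introduces a small k bias)
        covered = 0
        reps = 20
        for rep in range(reps):
            scenario = SimScenario(seed=100 + rep, sigma2=0.25, allow_nonmonotone=True)
            ds, _ = generate_dataset(scenario)
            from trapnet import impute_missing

            ds = impute_missing(ds)
            post = fit_growth_model(
                ds, ds.registry.site_ids, ds.years, MCMCConfig.fast(seed=rep)
            )
            lo, hi = np.quantile(post.k, [0.025, 0.975])
            covered += lo <= 1.5 <= hi
        assert covered >= 0.9 * reps

    def test_posterior_serialization_round_trip(self, small_dataset, fast_mcmc, tmp_path):
        ds, _ = small_dataset
        post = fit_growth_model(ds, ds.registry.site_ids[:4], [2021, 2022], fast_mcmc)
        post.to_csv(tmp_path / "posterior.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "posterior.csv")
        assert len(back) == post.n_draws
        np.testing.assert_allclose(back["k"].to_numpy(), post.k)

    def test_training_site_prediction_matches_fit(self, small_dataset, fast_mcmc):
        ds, _ = small_dataset
        sites = ds.registry.site_ids[:4]
        post = fit_growth_model(ds, sites, [2021, 2022], fast_mcmc)
        pred = predict_cumulative(post, post.train_registry, weeks=range(1, 9))
        curves = logistic_mean(
            np.arange(1, 9)[None, None, :],
            post.beta[:, :, None],
            post.gamma[:, :, None],
            post.k[:, None, None],
        )
        np.testing.assert_allclose(pred.mean, curves.mean(axis=0), rtol=1e-8)
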