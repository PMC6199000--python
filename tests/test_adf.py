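"""Assumed-density filter: prediction moments, updates, full runs."""

import numpy as np
import pytest
from conftest import make_belief
from reference_kf import textbook_kalman

from seizurepath import adf, model
from seizurepath.adf import (FilterConfig, GaussianBelief, NoiseSpec,
                             initialize, predict, reconstruct_forward,
                             run_filter, run_filter_array, update)
from seizurepath.model import N_X, N_XI, build_matrices, reference_params, simulate
from seizurepath.validation import mc_propagate_belief


@pytest.fixture(scope="module")
def q_small():
    return np.diag(np.full(N_XI, 1e-10))


class TestPredict:
    def test_linear_model_is_kalman_prediction(self, mats400, q_small):
        """With B = 0 the prediction is exactly (A mu, A P A' + Q)."""
        rng = np.random.default_rng(0)
        belief = make_belief(rng, 3e-3)
        mats = model.SystemMatrices(A=mats400.A, B=np.zeros((N_XI, N_XI)),
                                    C=mats400.C, H=mats400.H, dt=mats400.dt)
        out = predict(belief, mats, q_small)
        assert np.allclose(out.mean, mats.A @ belief.mean, atol=1e-15)
        expect = mats.A @ belief.cov @ mats.A.T + q_small
        assert np.allclose(out.cov, expect, atol=1e-18)

    def test_zero_covariance_is_deterministic_step(self, mats400, q_small):
        """A point belief propagates like one noise-free simulation step."""
        theta = reference_params().as_vector()
        mu = np.zeros(N_XI)
        mu[:N_X] = np.random.default_rng(1).normal(0, 2e-3, N_X)
        mu[N_X:] = theta
        belief = GaussianBelief(mean=mu, cov=np.zeros((N_XI, N_XI)))
        out = predict(belief, mats400, q_small)
        # one Euler step computed from the model directly
        sim = simulate(np.tile(theta, (1, 1)), fs=400.0,
                       x0=mu[:N_X])
        assert np.allclose(out.mean[:N_X], sim.states[0, :N_X], atol=1e-15)
        assert np.allclose(out.cov, q_small, atol=1e-13)

    def test_moments_match_monte_carlo(self, mats400, q_small, sigmoid):
        """Exact moment propagation vs sampling across covariance scales."""
        rng = np.random.default_rng(42)
        for trial, scale in enumerate([1e-4, 3e-3, 2e-2]):
            belief = make_belief(rng, scale)
            pred = predict(belief, mats400, q_small, sigmoid)
            m_mc, c_mc, se_m, se_c = mc_propagate_belief(
                belief, mats400, q_small, sigmoid, n=10 ** 5, seed=trial)
            assert np.all(np.abs(pred.mean - m_mc) <= 3 * se_m)
            assert np.all(np.abs(pred.cov - c_mc) <= 3 * se_c)

    def test_output_covariance_symmetric_psd(self, mats400, q_small):
        rng = np.random.default_rng(9)
        for _ in range(5):
            out = predict(make_belief(rng, 1e-2), mats400, q_small)
            assert np.max(np.abs(out.cov - out.cov.T)) <= 1e-10
            assert np.linalg.eigvalsh(out.cov).min() >= -1e-12 * np.trace(out.cov)


class TestUpdate:
    def test_scalar_textbook_case(self):
        """Prior N(0,1), H selecting one state, R=1, y=2 -> N(1, 0.5)."""
        cov = np.eye(N_XI) * 1e-18
        cov[0, 0] = 1.0
        prior = GaussianBelief(mean=np.zeros(N_XI), cov=cov)
        H = np.zeros(N_XI)
        H[0] = 1.0
        post, (K, innov, s) = update(prior, 2.0, H, 1.0)
        assert post.mean[0] == pytest.approx(1.0, rel=1e-12)
        assert post.cov[0, 0] == pytest.approx(0.5, rel=1e-12)
        assert innov == pytest.approx(2.0)
        assert s == pytest.approx(2.0)

    def test_huge_r_leaves_prior(self, mats400):
        rng = np.random.default_rng(2)
        prior = make_belief(rng, 1e-3)
        post, _ = update(prior, 0.05, mats400.H, 1e12)
        assert np.allclose(post.mean, prior.mean, atol=1e-8)
        assert np.allclose(post.cov, prior.cov, rtol=1e-8, atol=1e-15)

    def test_never_increases_marginal_variance(self, mats400):
        rng = np.random.default_rng(3)
        for _ in range(5):
            prior = make_belief(rng, 5e-3)
            post, _ = update(prior, rng.normal(0, 0.01), mats400.H, 1e-8)
            assert np.all(np.diag(post.cov) <= np.diag(prior.cov) + 1e-18)

    def test_rejects_bad_r(self, mats400):
        prior = GaussianBelief(np.zeros(N_XI), np.eye(N_XI))
        with pytest.raises(ValueError):
            update(prior, 0.0, mats400.H, 0.0)


class TestInitialize:
    def test_r_override(self):
        cfg = FilterConfig(r_override=2.5e-7)
        _, noise = initialize(np.random.default_rng(0).normal(0, 1e-3, 1000),
                              400.0, cfg)
        assert noise.R == pytest.approx(2.5e-7)

    def test_white_noise_variance_recovered(self):
        sigma = 3e-4
        y = np.random.default_rng(1).normal(0.0, sigma, 10_000)
        cfg = FilterConfig(r_highpass_hz=None)
        _, noise = initialize(y, 400.0, cfg)
        assert noise.R == pytest.approx(sigma ** 2, rel=0.10)

    def test_p0_structure(self):
        cfg = FilterConfig(p0_state=1e-5, p0_param_frac=0.3)
        belief, _ = initialize(np.random.default_rng(2).normal(0, 1e-3, 500),
                               400.0, cfg)
        assert np.count_nonzero(belief.cov - np.diag(np.diag(belief.cov))) == 0
        assert np.allclose(np.diag(belief.cov)[:N_X], 1e-5)
        theta0 = np.asarray(cfg.theta0)
        assert np.allclose(np.diag(belief.cov)[N_X:],
                           (0.3 * np.abs(theta0)) ** 2)
        assert np.allclose(belief.mean[N_X:], theta0)
        assert np.allclose(belief.mean[:N_X], 0.0)

    def test_constant_baseline_rejected(self):
        with pytest.raises(ValueError):
            initialize(np.ones(1000), 400.0, FilterConfig())


class TestRunFilter:
    def test_nan_sample_invalidates(self):
        y = np.random.default_rng(0).normal(0, 1e-3, 500)
        y[300] = np.nan
        cfg = FilterConfig(r_override=1e-8)
        belief0, noise = initialize(y[:100], 400.0, cfg)
        est = run_filter_array(y, 400.0, belief0, noise, cfg)
        assert not est.valid
        assert est.n_valid == 300
        assert est.diagnostics.stability_flag[:300].all()
        assert not est.diagnostics.stability_flag[300:].any()

    def test_empty_stream_rejected(self):
        cfg = FilterConfig(r_override=1e-8)
        belief0, noise = initialize(np.random.default_rng(0).normal(0, 1, 100),
                                    400.0, cfg)
        with pytest.raises(ValueError):
            run_filter_array(np.array([]), 400.0, belief0, noise, cfg)

    def test_linear_limit_matches_textbook_kf(self):
        """Identity coupling: the ADF equals a standard Kalman filter."""
        fs = 400.0
        mats = build_matrices(dt=1.0 / fs)
        rng = np.random.default_rng(7)
        n = 2000
        y = rng.normal(0.0, 1e-3, n)
        cfg = FilterConfig(linear=True, r_override=1e-8, q_state_sd=1e-4,
                           q_param_sd=1e-6)
        belief0, noise = initialize(y[:200], fs, cfg)
        est = run_filter_array(y, fs, belief0, noise, cfg)
        F = mats.A + mats.B @ mats.C
        means, covs = textbook_kalman(y, F, mats.H, noise.Q, noise.R,
                                      belief0.mean, belief0.cov)
        assert est.valid
        assert np.max(np.abs(est.means - means)) < 1e-10
        assert np.max(np.abs(est.variances
                             - covs[:, np.arange(N_XI), np.arange(N_XI)])) < 1e-10

    def test_covariance_health_over_run(self):
        """P stays symmetric-PSD throughout a nonlinear run (spot-checked
        via the per-sample variances being finite and non-negative)."""
        sim = simulate(reference_params(), fs=400.0, duration=3.0,
                       process_noise_sd=1e-3, obs_noise_sd=1e-4, seed=0)
        cfg = FilterConfig(r_override=1e-8, q_state_sd=1e-3, q_param_sd=1e-6)
        belief0, noise = initialize(sim.observation[:400], 400.0, cfg)
        est = run_filter_array(sim.observation, 400.0, belief0, noise, cfg)
        assert est.valid
        assert np.isfinite(est.variances).all()
        assert (est.variances >= 0).all()

    def test_parameter_recovery_smoke(self):
        """Constant-theta recovery within 10% on one seeded run."""
        fs = 400.0
        rng = np.random.default_rng(0)
        nominal = reference_params().as_vector()
        truth = nominal * (1 + rng.uniform(-0.15, 0.15, 5))
        sim = simulate(truth, fs=fs, duration=40.0, process_noise_sd=1e-3,
                       obs_noise_sd=1e-4, seed=1000)
        cfg = FilterConfig(theta0=nominal, r_override=1e-8, q_state_sd=1e-3,
                           q_param_sd=1e-7)
        belief0, noise = initialize(sim.observation[:4000], fs, cfg)
        est = run_filter_array(sim.observation, fs, belief0, noise, cfg)
        assert est.valid
        n = est.means.shape[0]
        theta_hat = est.theta[2 * n // 3:].mean(axis=0)
        assert np.all(np.abs(theta_hat - truth) / np.abs(truth) < 0.10)

    def test_innovation_whiteness_matched_model(self):
        """Lag-1 innovation autocorrelation is small on matched data."""
        fs = 400.0
        sim = simulate(reference_params(), fs=fs, duration=25.0,
                       process_noise_sd=1e-3, obs_noise_sd=1e-4, seed=3)
        cfg = FilterConfig(r_override=1e-8, q_state_sd=1e-3, q_param_sd=1e-8)
        belief0, noise = initialize(sim.observation[:4000], fs, cfg)
        est = run_filter_array(sim.observation, fs, belief0, noise, cfg)
        inn = est.diagnostics.innovation[1000:]
        rho1 = np.corrcoef(inn[:-1], inn[1:])[0, 1]
        assert abs(rho1) < 0.1

    def test_run_filter_determinism(self):
        sim = simulate(reference_params(), fs=400.0, duration=2.0,
                       process_noise_sd=1e-3, obs_noise_sd=1e-4, seed=5)
        cfg = FilterConfig(r_override=1e-8)
        belief0, noise = initialize(sim.observation[:200], 400.0, cfg)
        a = run_filter_array(sim.observation, 400.0, belief0, noise, cfg)
        b = run_filter_array(sim.observation, 400.0, belief0, noise, cfg)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.variances, b.variances)


class TestReconstructForward:
    def test_ground_truth_reconstruction_correlates(self):
        """Driving the model with the true theta(t) reproduces the signal."""
        fs = 400.0
        theta = np.tile(reference_params().as_vector(), (int(5 * fs), 1))
        sim = simulate(theta, fs=fs)
        est = adf.TrajectoryEstimate(
            time=np.arange(theta.shape[0]) / fs,
            means=np.hstack([sim.states[:, :N_X], theta]),
            variances=np.zeros((theta.shape[0], N_XI)),
            diagnostics=adf.FilterDiagnostics(
                innovation=np.zeros(theta.shape[0]),
                gain=np.zeros((theta.shape[0], N_XI)),
                stability_flag=np.ones(theta.shape[0], dtype=bool), mse=0.0),
            valid=True, n_valid=theta.shape[0], fs=fs)
        recon = reconstruct_forward(est)
        r = np.corrcoef(recon.observation, sim.observation)[0, 1]
        assert r >= 0.99

    def test_subthreshold_is_bounded_nonoscillatory(self):
        fs = 400.0
        theta = reference_params(u=2e-3).as_vector()
        est = adf.TrajectoryEstimate(
            time=np.arange(int(4 * fs)) / fs,
            means=np.hstack([np.zeros((int(4 * fs), N_X)),
                             np.tile(theta, (int(4 * fs), 1))]),
            variances=np.zeros((int(4 * fs), N_XI)),
            diagnostics=adf.FilterDiagnostics(
                innovation=np.zeros(int(4 * fs)),
                gain=np.zeros((int(4 * fs), N_XI)),
                stability_flag=np.ones(int(4 * fs), dtype=bool), mse=0.0),
            valid=True, n_valid=int(4 * fs), fs=fs)
        recon = reconstruct_forward(est)
        y = recon.observation
        assert np.isfinite(y).all()
        assert np.max(np.abs(y)) < 0.05
        assert y[-int(fs):].std() < 1e-6     # settled, no sustained oscillation

    def test_invalid_estimate_rejected(self):
        est = adf.TrajectoryEstimate(
            time=np.zeros(1), means=np.zeros((1, N_XI)),
            variances=np.zeros((1, N_XI)),
            diagnostics=adf.FilterDiagnostics(np.zeros(1), np.zeros((1, N_XI)),
                                              np.zeros(1, dtype=bool), 0.0),
            valid=False, n_valid=0, fs=400.0)
        with pytest.raises(ValueError):
            reconstruct_forward(est)

    def test_repeated_call_identical(self):
        fs = 400.0
        theta = np.tile(reference_params().as_vector(), (800, 1))
        est = adf.TrajectoryEstimate(
            time=np.arange(800) / fs,
            means=np.hstack([np.zeros((800, N_X)), theta]),
            variances=np.zeros((800, N_XI)),
            diagnostics=adf.FilterDiagnostics(np.zeros(800),
                                              np.zeros((800, N_XI)),
                                              np.ones(800, dtype=bool), 0.0),
            valid=True, n_valid=800, fs=fs)
        a = reconstruct_forward(est)
        b = reconstruct_forward(est)
        assert np.array_equal(a.observation, b.observation)
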