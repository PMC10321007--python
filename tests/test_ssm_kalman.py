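import numpy as np
import pytest
from scipy import stats

from trackssm.ssm_kalman import (
    KalmanModel,
    fit_variances_mle,
    kalman_loglik,
    smooth_states,
)
from trackssm.simulate import SimParams, simulate_accumulation
from trackssm.trajectories import CellTrack, TimeGrid, compute_velocity
from trackssm.ssm_bayes import estimate_start_from_intervals


def joint_gaussian_oracle(grid, sigma2_beta, sigma2_y, init_var=None):
    """Joint covariance of (y_post, beta) assembled from first principles.

    beta follows a random walk from N(0, init_var) at onset with increment
    variance sigma2_beta; y_post adds iid observation noise.
    """
    if init_var is None:
        init_var = sigma2_beta
    n = grid.n_beam
    idx = np.arange(n)
    # Cov(beta_i, beta_j) = init_var + sigma2_beta * min(i, j)
    cov_beta = init_var + sigma2_beta * np.minimum.outer(idx, idx)
    cov_y = cov_beta + sigma2_y * np.eye(n)
    return cov_beta, cov_y


def brute_loglik(grid, y, sigma2_beta, sigma2_y, init_var=None):
    t0_pos = grid.onset_velocity_index - 1
    pre, post = y[:t0_pos], y[t0_pos:]
    _, cov_y = joint_gaussian_oracle(grid, sigma2_beta, sigma2_y, init_var)
    ll = stats.norm.logpdf(pre, 0.0, np.sqrt(sigma2_y)).sum()
    ll += stats.multivariate_normal.logpdf(post, mean=np.zeros(len(post)), cov=cov_y)
    return float(ll)


def brute_smoother(grid, y, sigma2_beta, sigma2_y, init_var=None):
    t0_pos = grid.onset_velocity_index - 1
    post = y[t0_pos:]
    cov_beta, cov_y = joint_gaussian_oracle(grid, sigma2_beta, sigma2_y, init_var)
    solve = np.linalg.solve(cov_y, post)
    mean = cov_beta @ solve
    cov_post = cov_beta - cov_beta @ np.linalg.solve(cov_y, cov_beta)
    return mean, np.diag(cov_post)


def _velocity(grid, y):
    d0 = 10.0 + max(0.0, -np.min(np.cumsum(y)))  # keep distances non-negative
    d = np.concatenate([[d0], d0 + np.cumsum(y)])
    return compute_velocity(CellTrack("c", "o", d), grid)


class TestLoglikOracle:
    def test_matches_brute_force_T6(self, tiny_grid, rng):
        for _ in range(10):
            s2b, s2y = rng.uniform(0.01, 1.0, size=2)
            y = rng.normal(0, 1, size=tiny_grid.n_velocity)
            vel = _velocity(tiny_grid, y)
            model = KalmanModel(grid=tiny_grid, sigma2_beta=s2b, sigma2_y=s2y)
            assert kalman_loglik(model, vel) == pytest.approx(
                brute_loglik(tiny_grid, y, s2b, s2y), abs=1e-8
            )

    def test_sigma_y_doubling_pre_onset_term(self, tiny_grid):
        # With y = 0 pre-onset each pre-onset term is -0.5*log(2*pi*s2y):
        # doubling sigma_y changes it by exactly -0.5*log(4) per term.
        y = np.concatenate([np.zeros(2), np.array([0.5, 0.4, 0.3, 0.2])])
        vel = _velocity(tiny_grid, y)
        m1 = KalmanModel(grid=tiny_grid, sigma2_beta=0.1, sigma2_y=0.25)
        m2 = KalmanModel(grid=tiny_grid, sigma2_beta=0.1, sigma2_y=1.0)
        post1 = brute_loglik(tiny_grid, y, 0.1, 0.25) - stats.norm.logpdf(
            np.zeros(2), 0, 0.5
        ).sum()
        post2 = brute_loglik(tiny_grid, y, 0.1, 1.0) - stats.norm.logpdf(np.zeros(2), 0, 1.0).sum()
        diff_pre = (kalman_loglik(m1, vel) - post1) - (kalman_loglik(m2, vel) - post2)
        assert diff_pre == pytest.approx(2 * (-0.5 * np.log(0.25) + 0.5 * np.log(1.0)), abs=1e-8)

    def test_static_coefficient_profile_likelihood(self, tiny_grid):
        # sigma2_beta = 0 with diffuse start: the coefficient is one unknown
        # constant, so the smoothed mean converges to the post-onset average.
        y = np.array([0.1, -0.1, 0.5, 0.7, 0.6, 0.4])
        vel = _velocity(tiny_grid, y)
        model = KalmanModel(grid=tiny_grid, sigma2_beta=0.0, sigma2_y=0.3, diffuse_init=True)
        ss = smooth_states(model, vel)
        post_mean = y[2:].mean()
        np.testing.assert_allclose(ss.beta_mean, post_mean, atol=1e-5)

    def test_nonfinite_rejected(self, tiny_grid):
        y = np.array([0.1, np.nan, 0.5, 0.7, 0.6, 0.4])
        d = np.concatenate([[50.0], 50.0 + np.cumsum(np.nan_to_num(y))])
        track = CellTrack("c", "o", d)
        vel = compute_velocity(track, tiny_grid)
        vel.y[1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            kalman_loglik(KalmanModel(grid=tiny_grid), vel)


class TestSmootherOracle:
    def test_matches_conditional_gaussian_T6(self, tiny_grid, rng):
        for _ in range(10):
            s2b, s2y = rng.uniform(0.05, 1.0, size=2)
            y = rng.normal(0, 1, size=tiny_grid.n_velocity)
            vel = _velocity(tiny_grid, y)
            ss = smooth_states(KalmanModel(grid=tiny_grid, sigma2_beta=s2b, sigma2_y=s2y), vel)
            mean, var = brute_smoother(tiny_grid, y, s2b, s2y)
            np.testing.assert_allclose(ss.beta_mean, mean, atol=1e-8)
            np.testing.assert_allclose(ss.beta_var, var, atol=1e-8)

    def test_zero_velocity_zero_beta(self, tiny_grid):
        vel = _velocity(tiny_grid, np.zeros(6))
        ss = smooth_states(KalmanModel(grid=tiny_grid, sigma2_beta=0.2, sigma2_y=0.2), vel)
        np.testing.assert_allclose(ss.beta_mean, 0.0, atol=1e-12)
        summary = ss.to_summary()
        np.testing.assert_allclose(
            summary.beta["upper99"], -summary.beta["lower99"], atol=1e-12
        )

    def test_smoother_variance_below_filter_variance(self, default_grid, rng):
        from trackssm._ssmcore import rts_smoother, rw_filter_dense

        y = rng.normal(0, 0.5, size=default_grid.n_velocity)
        fr = rw_filter_dense(y[29:], obs_var=0.09, q=0.01, init_var=0.01)
        _, P_s = rts_smoother(fr)
        assert np.all(P_s <= fr.P_filt + 1e-12)

    def test_noiseless_linear_decline_constant_beta(self, default_grid):
        # distance declines at 0.4 um/min from onset: beta ~ -0.4 throughout
        t0 = default_grid.onset_velocity_index
        y = np.zeros(default_grid.n_velocity)
        y[t0 - 1 :] = -0.4
        vel = _velocity(default_grid, y)
        fit = fit_variances_mle(vel, default_grid)
        ss = smooth_states(fit.model, vel)
        np.testing.assert_allclose(ss.beta_mean, -0.4, atol=0.02)


class TestVarianceMle:
    def test_recovers_known_variances(self, default_grid):
        # average of log-scale MLEs over replicates should sit near truth
        true_s2b, true_s2y = 0.02, 0.09
        t0_pos = default_grid.onset_velocity_index - 1
        errs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            beta = np.cumsum(r.normal(0, np.sqrt(true_s2b), size=default_grid.n_beam))
            y = r.normal(0, np.sqrt(true_s2y), size=default_grid.n_velocity)
            y[t0_pos:] += beta
            fit = fit_variances_mle(_velocity(default_grid, y), default_grid)
            assert fit.converged
            errs.append(
                [
                    np.log(fit.model.sigma2_beta) - np.log(true_s2b),
                    np.log(fit.model.sigma2_y) - np.log(true_s2y),
                ]
            )
        mean_err = np.abs(np.mean(errs, axis=0))
        # the RW variance is weakly identified from one series (large spread,
        # mild downward small-sample bias); the noise variance is sharp
        assert mean_err[0] < 0.6
        assert mean_err[1] < 0.1

    def test_scaling_pre_onset_increases_sigma_y(self, default_grid, rng):
        y = rng.normal(0, 0.3, size=default_grid.n_velocity)
        fit1 = fit_variances_mle(_velocity(default_grid, y), default_grid)
        y2 = y.copy()
        y2[: default_grid.onset_velocity_index - 1] *= 2.0
        fit2 = fit_variances_mle(_velocity(default_grid, y2), default_grid)
        assert fit2.model.sigma2_y > fit1.model.sigma2_y

    def test_boundary_sigma_beta_zero(self, default_grid, rng):
        # truth has a static coefficient: fitted RW variance should be tiny
        y = rng.normal(0, 0.3, size=default_grid.n_velocity)
        y[default_grid.onset_velocity_index - 1 :] += -0.5
        fit = fit_variances_mle(_velocity(default_grid, y), default_grid)
        assert fit.converged
        assert fit.model.sigma2_beta < 0.01

    def test_too_few_post_onset_points(self):
        grid = TimeGrid(n_frames=10, onset_velocity_index=5)
        vel = _velocity(grid, np.zeros(9))
        with pytest.raises(ValueError, match="post-onset"):
            fit_variances_mle(vel, grid)


class TestModelValidation:
    def test_negative_variance_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            KalmanModel(grid=tiny_grid, sigma2_beta=-1.0, sigma2_y=1.0)

    def test_both_zero_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            KalmanModel(grid=tiny_grid, sigma2_beta=0.0, sigma2_y=0.0)


class TestKalmanStartTime:
    def test_detects_simulated_start(self, default_grid):
        params = SimParams(
            grid=default_grid,
            organelles_per_cell=1,
            initial_distances=[12.0],
            sigma_w=0.1,
            sigma_y=0.1,
            signal_speed=0.8,
            seed=2,
        )
        ts, truth = simulate_accumulation(params)
        vel = compute_velocity(ts.tracks[0], default_grid)
        fit = fit_variances_mle(vel, default_grid)
        summary = smooth_states(fit.model, vel).to_summary()
        est = estimate_start_from_intervals(summary, default_grid)
        assert est.method == "kalman"
        assert est.is_finite
        assert abs(est.start_min - truth.organelles[0].true_start_min) <= 5
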