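import math

import numpy as np
import pandas as pd
import pytest

from trackssm.simulate import SimParams, simulate_accumulation
from trackssm.ssm_bayes import (
    IndividualModelSpec,
    McmcConfig,
    PosteriorDraws,
    PosteriorSummary,
    StartTimeEstimate,
    estimate_start_from_intervals,
    fit_individual,
    reconstruct_distance,
    summarize_posterior,
)
from trackssm.ssm_kalman import KalmanModel, smooth_states
from trackssm.trajectories import CellTrack, TimeGrid, compute_velocity


def _draws_from_beta(beta, grid, alpha=None):
    n = beta.shape[0]
    T = grid.n_velocity
    if alpha is None:
        alpha = np.zeros((n, T))
        alpha[:, grid.onset_velocity_index - 1 :] = beta
    return PosteriorDraws(
        beta=beta,
        alpha=alpha,
        w=np.zeros((n, T)),
        sigma_w=np.full(n, 0.1),
        sigma_beta=np.full(n, 0.1),
        sigma_y=np.full(n, 0.1),
        grid=grid,
        chains=1,
        samples_per_chain=n,
    )


def _velocity(grid, y):
    d0 = 10.0 + max(0.0, -np.min(np.cumsum(y)))
    d = np.concatenate([[d0], d0 + np.cumsum(y)])
    return compute_velocity(CellTrack("c", "o", d), grid)


class TestSummarize:
    def test_degenerate_draws_collapse(self, tiny_grid):
        beta = np.full((100, tiny_grid.n_beam), -0.3)
        summary = summarize_posterior(_draws_from_beta(beta, tiny_grid))
        for L in (90, 95, 99):
            np.testing.assert_array_equal(summary.beta[f"lower{L}"], -0.3)
            np.testing.assert_array_equal(summary.beta[f"upper{L}"], -0.3)
        np.testing.assert_array_equal(summary.beta["median"], -0.3)

    def test_standard_normal_quantiles(self, tiny_grid, rng):
        beta = rng.standard_normal((200_000, tiny_grid.n_beam))
        summary = summarize_posterior(_draws_from_beta(beta, tiny_grid))
        np.testing.assert_allclose(summary.beta["upper99"], 2.576, atol=0.04)
        np.testing.assert_allclose(summary.beta["lower95"], -1.960, atol=0.04)

    def test_interval_nesting(self, tiny_grid, rng):
        beta = rng.normal(0, 1, size=(500, tiny_grid.n_beam))
        summary = summarize_posterior(_draws_from_beta(beta, tiny_grid))
        b = summary.beta
        assert (b["lower99"] <= b["lower95"]).all()
        assert (b["lower95"] <= b["lower90"]).all()
        assert (b["lower90"] <= b["median"]).all()
        assert (b["median"] <= b["upper90"]).all()
        assert (b["upper90"] <= b["upper95"]).all()
        assert (b["upper95"] <= b["upper99"]).all()


def _summary_from_uppers(grid, upper99, upper95=None, upper90=None):
    idx = pd.Index(grid.beam_velocity_indices, name="t")
    n = len(idx)
    upper95 = upper99 - 0.1 if upper95 is None else upper95
    upper90 = upper95 - 0.1 if upper90 is None else upper90
    beta = pd.DataFrame(
        {
            "median": np.zeros(n),
            "lower90": upper90 - 1,
            "upper90": upper90,
            "lower95": upper95 - 1,
            "upper95": upper95,
            "lower99": upper99 - 1,
            "upper99": upper99,
        },
        index=idx,
    )
    return PosteriorSummary(
        beta=beta, alpha=None, w=None, sigma={}, levels=(90, 95, 99), grid=grid
    )


class TestStartRule:
    def test_first_negative_upper99(self, default_grid):
        upper99 = np.ones(default_grid.n_beam)
        upper99[40 - default_grid.onset_velocity_index :] = -0.5  # t = 40 onward
        est = estimate_start_from_intervals(_summary_from_uppers(default_grid, upper99), default_grid)
        assert est.start_min == 11.0
        assert est.threshold_used == 99

    def test_fallback_to_95(self, default_grid):
        n = default_grid.n_beam
        upper99 = np.ones(n)
        upper95 = np.ones(n)
        upper95[50 - default_grid.onset_velocity_index :] = -0.2  # t = 50 onward
        est = estimate_start_from_intervals(
            _summary_from_uppers(default_grid, upper99, upper95=upper95, upper90=upper95 - 0.1),
            default_grid,
        )
        assert est.start_min == 21.0
        assert est.threshold_used == 95

    def test_all_positive_infinity(self, default_grid):
        n = default_grid.n_beam
        est = estimate_start_from_intervals(
            _summary_from_uppers(default_grid, np.ones(n), np.full(n, 0.5), np.full(n, 0.2)),
            default_grid,
        )
        assert est.start_min == math.inf
        assert est.threshold_used is None

    def test_strictly_negative_required(self, default_grid):
        n = default_grid.n_beam
        est = estimate_start_from_intervals(
            _summary_from_uppers(default_grid, np.zeros(n), np.zeros(n), np.zeros(n)),
            default_grid,
        )
        assert est.start_min == math.inf

    def test_threshold_monotonicity(self, default_grid, rng):
        # nested bounds (upper95 <= upper99): the 95% rule can never fire later
        for _ in range(20):
            upper99 = rng.normal(0.2, 0.5, size=default_grid.n_beam)
            upper95 = upper99 - rng.uniform(0, 0.3, size=default_grid.n_beam)
            starts = {}
            for level, bound in ((99, upper99), (95, upper95)):
                neg = np.flatnonzero(bound < 0)
                starts[level] = neg[0] if len(neg) else None
            if starts[99] is not None and starts[95] is not None:
                assert starts[95] <= starts[99]

    def test_escape_direction_uses_lower_bounds(self, default_grid):
        n = default_grid.n_beam
        summary = _summary_from_uppers(default_grid, np.ones(n), np.ones(n), np.ones(n))
        summary.beta["lower99"] = np.concatenate([np.full(10, -1.0), np.full(n - 10, 0.5)])
        est = estimate_start_from_intervals(summary, default_grid, direction="escape")
        assert est.threshold_used == 99
        assert est.start_min == 11.0


class TestStartTimeEstimateInvariants:
    def test_infinite_cannot_have_threshold(self):
        with pytest.raises(ValueError):
            StartTimeEstimate(start_min=math.inf, threshold_used=99, method="bayes")

    def test_finite_bayes_needs_threshold(self):
        with pytest.raises(ValueError):
            StartTimeEstimate(start_min=5.0, threshold_used=None, method="bayes")

    def test_heuristic_has_no_threshold(self):
        est = StartTimeEstimate(start_min=5.0, threshold_used=None, method="heuristic")
        assert est.is_finite


class TestFitIndividual:
    def test_sigma_fixed_reduction_matches_kalman_smoother(self, small_grid, rng):
        # with sigma_w = 0 enforced the model is linear-Gaussian: FFBS draws
        # are exact posterior samples, so their mean/SD must match the
        # smoother within Monte-Carlo error
        sb, sy = 0.15, 0.3
        y = rng.normal(0, sy, size=small_grid.n_velocity)
        y[small_grid.onset_velocity_index - 1 :] += np.cumsum(
            rng.normal(0, sb, size=small_grid.n_beam)
        )
        vel = _velocity(small_grid, y)
        mcmc = McmcConfig(chains=2, warmup=10, samples_per_chain=1500, seed=7)
        draws = fit_individual(
            vel, IndividualModelSpec(grid=small_grid), mcmc, fixed_sigmas=(0.0, sb, sy)
        )
        ss = smooth_states(
            KalmanModel(grid=small_grid, sigma2_beta=sb**2, sigma2_y=sy**2), vel
        )
        n = draws.n_draws
        mc_se = np.sqrt(ss.beta_var / n)
        assert np.all(np.abs(draws.beta.mean(axis=0) - ss.beta_mean) < 3.5 * mc_se)
        sd_se = np.sqrt(ss.beta_var / (2 * (n - 1)))
        assert np.all(np.abs(draws.beta.std(axis=0) - np.sqrt(ss.beta_var)) < 3.5 * sd_se)
        # w is pinned at zero in this reduction
        assert np.all(draws.w == 0)

    def test_zero_data_tight_priors_beta_near_zero(self, small_grid):
        vel = _velocity(small_grid, np.zeros(small_grid.n_velocity))
        draws = fit_individual(
            vel,
            IndividualModelSpec(grid=small_grid, prior_sd_scale=0.05),
            McmcConfig(chains=2, warmup=300, samples_per_chain=300, seed=3),
        )
        medians = np.median(draws.beta, axis=0)
        assert np.all(np.abs(medians) < 0.05)

    def test_reproducible_given_seed(self, small_grid, rng):
        y = rng.normal(0, 0.3, size=small_grid.n_velocity)
        vel = _velocity(small_grid, y)
        mcmc = McmcConfig(chains=2, warmup=100, samples_per_chain=100, seed=5)
        d1 = fit_individual(vel, IndividualModelSpec(grid=small_grid), mcmc)
        d2 = fit_individual(vel, IndividualModelSpec(grid=small_grid), mcmc)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.sigma_beta, d2.sigma_beta)

    def test_grid_mismatch_rejected(self, small_grid, tiny_grid, rng):
        vel = _velocity(tiny_grid, rng.normal(size=tiny_grid.n_velocity))
        with pytest.raises(ValueError, match="grid"):
            fit_individual(vel, IndividualModelSpec(grid=small_grid), McmcConfig())

    def test_simulated_pulse_recovery_and_coverage(self, small_grid):
        # 95% band should cover the true coefficient at most time points
        r = np.random.default_rng(0)
        true_beta = np.where(np.arange(small_grid.n_beam) >= 5, -0.5, 0.0)
        covered = []
        for rep in range(3):
            y = r.normal(0, np.sqrt(0.3**2 + 0.3**2), size=small_grid.n_velocity)
            y[small_grid.onset_velocity_index - 1 :] += true_beta
            vel = _velocity(small_grid, y)
            draws = fit_individual(
                vel,
                IndividualModelSpec(grid=small_grid),
                McmcConfig(chains=2, warmup=400, samples_per_chain=400, seed=rep),
            )
            summary = summarize_posterior(draws)
            covered.append(
                np.mean(
                    (summary.beta["lower95"].to_numpy() <= true_beta)
                    & (true_beta <= summary.beta["upper95"].to_numpy())
                )
            )
        assert np.mean(covered) > 0.8


class TestReconstructDistance:
    def test_zero_alpha_flat_band(self, tiny_grid):
        draws = _draws_from_beta(
            np.zeros((50, tiny_grid.n_beam)), tiny_grid, alpha=np.zeros((50, tiny_grid.n_velocity))
        )
        band = reconstruct_distance(draws, d0=4.2)
        np.testing.assert_array_equal(band["median"], 4.2)
        np.testing.assert_array_equal(band["upper99"], 4.2)

    def test_single_draw_collapses_to_cumsum(self, tiny_grid, rng):
        alpha = rng.normal(size=(1, tiny_grid.n_velocity))
        draws = _draws_from_beta(np.zeros((1, tiny_grid.n_beam)), tiny_grid, alpha=alpha)
        band = reconstruct_distance(draws, d0=1.0)
        expected = np.concatenate([[1.0], 1.0 + np.cumsum(alpha[0])])
        np.testing.assert_allclose(band["median"], expected)
        np.testing.assert_allclose(band["lower99"], expected)
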