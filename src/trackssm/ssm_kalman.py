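"""Linear-Gaussian variant without the white-noise velocity term.

The observed velocity is explained by the stimulus coefficient alone::

    y[t] ~ Normal(beta[t] * beam[t], sigma_y^2)
    beta[t0] ~ Normal(0, sigma_beta^2)           (diffuse option available)
    beta[t]  ~ Normal(beta[t-1], sigma_beta^2)   (t0 < t <= T)

Pre-onset velocities are iid ``N(0, sigma_y^2)``.  The two variances are
estimated by maximum likelihood (quasi-Newton on the log scale with
multi-start); states come from the exact fixed-interval smoother, and the
movement start time uses the same 99 -> 95 -> 90 upper-bound scan as the
Bayesian route, applied to Gaussian intervals ``mean +/- z * sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from trackssm._ssmcore import FilterResult, rts_smoother, rw_filter_dense
from trackssm.ssm_bayes import DEFAULT_LEVELS, PosteriorSummary, _quantile_frame  # noqa: F401
from trackssm.trajectories import TimeGrid, VelocitySeries

__all__ = [
    "KalmanModel",
    "KalmanFit",
    "SmoothedStates",
    "kalman_loglik",
    "fit_variances_mle",
    "smooth_states",
]

_DIFFUSE_VAR = 1e8


@dataclass(frozen=True)
class KalmanModel:
    grid: TimeGrid = field(default_factory=TimeGrid)
    sigma2_beta: float = 0.01
    sigma2_y: float = 0.09
    diffuse_init: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_beta < 0 or self.sigma2_y < 0:
            raise ValueError("variances must be non-negative")
        if self.sigma2_beta == 0 and self.sigma2_y == 0:
            raise ValueError("variances must not both be zero")

    @property
    def init_var(self) -> float:
        return _DIFFUSE_VAR if self.diffuse_init else self.sigma2_beta


@dataclass
class KalmanFit:
    model: KalmanModel
    loglik: float
    converged: bool
    n_starts_converged: int


@dataclass
class SmoothedStates:
    """Smoother output for the stimulus coefficient."""

    beta_mean: np.ndarray  # indices t0..T
    beta_var: np.ndarray
    fitted_y: np.ndarray  # indices 1..T (zero pre-onset)
    loglik: float
    model: KalmanModel

    def __post_init__(self) -> None:
        if np.any(self.beta_var < 0):
            raise ValueError("negative smoothed variance")

    def to_summary(self, levels: Iterable[int] = DEFAULT_LEVELS) -> PosteriorSummary:
        """Gaussian interval summary in the shared posterior-summary layout."""
        levels = tuple(sorted(set(int(L) for L in levels)))
        grid = self.model.grid
        sd = np.sqrt(self.beta_var)
        cols = {"median": self.beta_mean}
        for L in levels:
            z = stats.norm.ppf((1 + L / 100) / 2)
            cols[f"lower{L}"] = self.beta_mean - z * sd
            cols[f"upper{L}"] = self.beta_mean + z * sd
        beta = pd.DataFrame(cols, index=pd.Index(grid.beam_velocity_indices, name="t"))
        return PosteriorSummary(
            beta=beta,
            alpha=None,
            w=None,
            sigma={
                "sigma_beta": float(np.sqrt(self.model.sigma2_beta)),
                "sigma_y": float(np.sqrt(self.model.sigma2_y)),
            },
            levels=levels,
            grid=grid,
            method="kalman",
        )


def _check_velocity(model_grid: TimeGrid, velocity: VelocitySeries) -> np.ndarray:
    if velocity.grid != model_grid:
        raise ValueError("velocity series is not on the model's grid")
    y = np.asarray(velocity.y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("velocity contains non-finite values")
    return y


def _filter(model: KalmanModel, y: np.ndarray) -> tuple[float, FilterResult]:
    t0_pos = model.grid.onset_velocity_index - 1
    pre = y[:t0_pos]
    if model.sigma2_y <= 0:
        if np.any(pre != 0):
            return -np.inf, None  # type: ignore[return-value]
        ll_pre = 0.0
    else:
        ll_pre = float(
            -0.5 * (len(pre) * np.log(2 * np.pi * model.sigma2_y) + np.sum(pre**2) / model.sigma2_y)
        )
    fr = rw_filter_dense(
        y[t0_pos:], obs_var=model.sigma2_y, q=model.sigma2_beta, init_var=model.init_var
    )
    return ll_pre + fr.loglik, fr


def kalman_loglik(model: KalmanModel, velocity: VelocitySeries) -> float:
    """Exact Gaussian log-likelihood of the velocity series under *model*."""
    y = _check_velocity(model.grid, velocity)
    ll, _ = _filter(model, y)
    return ll


def fit_variances_mle(
    velocity: VelocitySeries,
    grid: TimeGrid,
    diffuse_init: bool = False,
    n_starts: int = 3,
) -> KalmanFit:
    """Maximum-likelihood estimation of the two variances.

    Maximises the likelihood over ``(log sigma2_beta, log sigma2_y)`` with
    L-BFGS from ``n_starts`` data-scaled starting points to guard against
    boundary minima; the best optimum is returned with a convergence flag.
    """
    velocity_y = _check_velocity(grid, velocity)
    n_post = grid.n_beam
    if n_post < 10:
        raise ValueError("need at least 10 post-onset velocity points")
    var_scale = max(float(np.var(velocity_y)), 1e-8)

    def neg_loglik(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 45):  # keep exp() finite; far outside any data scale
            return 1e12
        model = KalmanModel(
            grid=grid,
            sigma2_beta=float(np.exp(theta[0])),
            sigma2_y=float(np.exp(theta[1])),
            diffuse_init=diffuse_init,
        )
        ll, _ = _filter(model, velocity_y)
        return -ll if np.isfinite(ll) else 1e12

    starts = [
        np.log([var_scale * 0.1, var_scale]),
        np.log([var_scale, var_scale * 0.1]),
        np.log([var_scale * 1e-3, var_scale]),
    ][:n_starts]
    best = None
    n_converged = 0
    for x0 in starts:
        res = optimize.minimize(neg_loglik, x0, method="L-BFGS-B")
        if res.success:
            n_converged += 1
        if best is None or res.fun < best.fun:
            best = res
    model = KalmanModel(
        grid=grid,
        sigma2_beta=float(np.exp(best.x[0])),
        sigma2_y=float(np.exp(best.x[1])),
        diffuse_init=diffuse_init,
    )
    return KalmanFit(
        model=model,
        loglik=float(-best.fun),
        converged=n_converged > 0,
        n_starts_converged=n_converged,
    )


def smooth_states(model: KalmanModel, velocity: VelocitySeries) -> SmoothedStates:
    """Fixed-interval smoother for the stimulus coefficient."""
    y = _check_velocity(model.grid, velocity)
    ll, fr = _filter(model, y)
    m_s, P_s = rts_smoother(fr)
    t0_pos = model.grid.onset_velocity_index - 1
    fitted = np.zeros(len(y))
    fitted[t0_pos:] = m_s
    return SmoothedStates(beta_mean=m_s, beta_var=P_s, fitted_y=fitted, loglik=ll, model=model)
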