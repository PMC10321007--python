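"""Hierarchical per-cell "common dynamics" model.

Each cell is summarised by the dynamics of an imaginary organelle sitting at
distance zero from the stimulus.  Every real organelle follows the common
stimulus-coefficient trajectory, time-shifted by its own movement start, and
all organelles of the cell share one white-noise velocity series::

    y[t, n]        ~ Normal(alpha_each[t, n], sigma_y^2)
    alpha_each[t,n] = w[t] + beta_each[t, n] * beam[t]
    beta_each[t,n]  = 0                                   (t0 <= t < t*_n)
                    = beta_common[t - t*_n + t0]          (t*_n <= t <= T)
    w[t]           ~ Normal(0, sigma_w^2)                 (shared across n)
    beta_common    random walk from Normal(0, sigma_beta^2) at t0

where ``t*_n`` is organelle ``n``'s detected start index.  Start offsets use
the convention ``start[n] = t*_n - t0 + 2`` so that a zero-lag organelle
(``start[n] = 2``) tracks the common trajectory identically and the model
reduces to the individual model for a single such organelle.

The common distance is reconstructed per posterior draw as the cumulative
sum of the common velocity minus its pre-onset cumulative sum, which pins
the distance at the last pre-stimulus index to exactly zero.

Sampling mirrors the individual model: adaptive random-walk Metropolis on
the log-SDs against partially collapsed likelihoods (the shared white noise
collapsed for the noise SDs, the common coefficient collapsed for its
random-walk SD), with each collapsed block redrawn exactly afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from trackssm._ssmcore import backward_sample, rw_filter
from trackssm.ssm_bayes import (
    IndividualModelSpec,
    McmcConfig,
    _half_normal_logpdf,
    _quantile_frame,
    _split_rhat,
)
from trackssm.trajectories import TimeGrid

__all__ = [
    "CommonModelInput",
    "CommonDynamics",
    "map_start_offsets",
    "fit_common",
    "reconstruct_common_distance",
]


def map_start_offsets(starts_min: Sequence[float], grid: TimeGrid) -> np.ndarray:
    """Convert detector start times (minutes after onset) to model offsets.

    The offset convention is ``start[n] = t*_n - t0 + 2`` with ``t*_n`` the
    absolute velocity index of the detected movement onset, i.e.
    ``start[n] = start_min + 1``; an immediate responder (1 min) gets
    offset 2 and follows the common trajectory with no shift.  Non-finite
    starts and starts before onset are rejected.
    """
    offsets = []
    for s in starts_min:
        if not math.isfinite(s):
            raise ValueError("infinite start times must be excluded before the common model")
        off = int(round(s / grid.frame_interval)) + 1
        if off < 2:
            raise ValueError(f"start offset {off} < 2: movement before stimulus onset")
        offsets.append(off)
    return np.asarray(offsets, dtype=int)


@dataclass
class CommonModelInput:
    """Velocity matrix of one cell plus per-organelle start offsets."""

    velocities: np.ndarray  # (T, N)
    start_offsets: np.ndarray  # (N,) integers >= 2
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.start_offsets = np.asarray(self.start_offsets, dtype=int)
        if self.velocities.ndim != 2 or self.velocities.shape[0] != self.grid.n_velocity:
            raise ValueError(
                f"velocities must be (T={self.grid.n_velocity}, N), got {self.velocities.shape}"
            )
        if len(self.start_offsets) != self.velocities.shape[1]:
            raise ValueError("one start offset per organelle required")
        if np.any(self.start_offsets < 2):
            raise ValueError("start offsets must be >= 2")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities contain non-finite values")

    @property
    def n_organelles(self) -> int:
        return self.velocities.shape[1]

    @property
    def start_indices(self) -> np.ndarray:
        """Absolute velocity index t*_n of each organelle's movement onset."""
        return self.start_offsets + self.grid.onset_velocity_index - 2


@dataclass
class CommonDynamics:
    """Posterior summaries of a cell's common dynamics."""

    beta: pd.DataFrame  # indices t0..T
    alpha: pd.DataFrame  # indices 1..T
    w: pd.DataFrame  # indices 1..T
    dist: pd.DataFrame  # indices 1..T, zero at t0-1
    sigma: dict[str, float]
    levels: tuple[int, ...]
    grid: TimeGrid
    rhat: dict[str, float]
    converged: bool
    # raw pooled draws kept for downstream reconstruction / diagnostics
    beta_draws: np.ndarray
    alpha_draws: np.ndarray
    sigma_draws: np.ndarray  # columns sigma_w, sigma_beta, sigma_y


def _beta_each_matrix(beta_common: np.ndarray, inp: CommonModelInput) -> np.ndarray:
    """Expand a common-coefficient path to the (T, N) per-organelle matrix."""
    grid = inp.grid
    T = grid.n_velocity
    out = np.zeros((T, inp.n_organelles))
    t0 = grid.onset_velocity_index
    for n, t_star in enumerate(inp.start_indices):
        # velocity index t in [t_star, T] maps to common position t - t_star
        lo = max(t_star, t0)
        if lo > grid.last_velocity_index:
            continue
        n_obs = grid.last_velocity_index - lo + 1
        out[lo - 1 :, n] = beta_common[lo - t_star : lo - t_star + n_obs]
    return out


def _obs_mapping(inp: CommonModelInput) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row/column indices of velocity entries that observe the common path.

    Returns (rows, cols, split) where ``np.split(values, split)`` groups the
    flattened observations by common-path position ``0..n_beam-1``.
    """
    grid = inp.grid
    T = grid.last_velocity_index
    per_step: list[list[tuple[int, int]]] = [[] for _ in range(grid.n_beam)]
    for n, t_star in enumerate(inp.start_indices):
        for t in range(max(t_star, grid.onset_velocity_index), T + 1):
            per_step[t - t_star].append((t - 1, n))
    rows, cols, counts = [], [], []
    for step in per_step:
        counts.append(len(step))
        for r, c in step:
            rows.append(r)
            cols.append(c)
    split = np.cumsum(counts)[:-1]
    return np.asarray(rows, dtype=int), np.asarray(cols, dtype=int), split


def _noise_loglik(e: np.ndarray, sw2: float, sy2: float) -> float:
    """Log-density of residuals with the shared white noise integrated out.

    Rows of ``e`` (one per time point) are jointly N(0, sy2*I + sw2*J).
    """
    T, N = e.shape
    if sy2 <= 0:
        return -np.inf
    denom = sy2 + N * sw2
    logdet = (N - 1) * np.log(sy2) + np.log(denom)
    rowsum = e.sum(axis=1)
    quad = ((e**2).sum() - float(rowsum @ rowsum) * sw2 / denom) / sy2
    return float(-0.5 * (T * N * np.log(2 * np.pi) + T * logdet + quad))


def _rw_adapt(step: float, accepted: bool, it: int) -> float:
    return float(np.exp(np.log(step) + (1.0 if accepted else -0.43) * 3.0 / (it + 10)))


def _run_common_chain(
    inp: CommonModelInput,
    prior_scale: float,
    warmup: int,
    samples: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    grid = inp.grid
    y = inp.velocities
    T, N = y.shape
    t0_pos = grid.onset_velocity_index - 1
    rows, cols, split = _obs_mapping(inp)
    obs_template: list[np.ndarray] = [np.empty(0)] * grid.n_beam

    data_sd = max(float(np.std(y)), 1e-3)
    theta_noise = np.log([data_sd / 2, data_sd / 2]) + 0.1 * rng.standard_normal(2)
    theta_beta = float(np.log(data_sd / 2) + 0.1 * rng.standard_normal())
    step_noise, step_beta = 0.3, 0.3
    beta_common = np.zeros(grid.n_beam)
    w = np.zeros(T)

    out_beta = np.empty((samples, grid.n_beam))
    out_w = np.empty((samples, T))
    out_sigma = np.empty((samples, 3))

    beta_each = _beta_each_matrix(beta_common, inp)
    ll_noise = None
    for it in range(warmup + samples):
        sw, sy = np.exp(theta_noise)
        sb = math.exp(theta_beta)

        # -- (sigma_w, sigma_y) | y, beta   (shared white noise collapsed)
        e = y - beta_each
        if ll_noise is None:
            ll_noise = _noise_loglik(e, sw**2, sy**2)
            ll_noise += _half_normal_logpdf(np.exp(theta_noise), prior_scale)
            ll_noise += float(np.sum(theta_noise))
        prop = theta_noise + step_noise * rng.standard_normal(2)
        sw_p, sy_p = np.exp(prop)
        lp = _noise_loglik(e, sw_p**2, sy_p**2)
        lp += _half_normal_logpdf(np.exp(prop), prior_scale) + float(np.sum(prop))
        accepted = np.log(rng.uniform()) < lp - ll_noise
        if accepted:
            theta_noise, ll_noise = prop, lp
            sw, sy = sw_p, sy_p
        if it < warmup:
            step_noise = _rw_adapt(step_noise, accepted, it)

        # -- w | y, beta, sigmas  (exact Gaussian conditional, shared over n)
        sw2, sy2 = sw**2, sy**2
        if sw2 <= 0:
            w = np.zeros(T)
        else:
            prec = 1.0 / sw2 + N / sy2
            mean = e.sum(axis=1) / sy2 / prec
            w = mean + math.sqrt(1.0 / prec) * rng.standard_normal(T)

        # -- sigma_beta | y, w, sigma_y  (common coefficient collapsed)
        r = y[rows, cols] - w[rows]
        obs = [a for a in np.split(r, split)]
        fr = rw_filter(obs, obs_var=sy2, q=sb**2, init_var=sb**2)
        ll_beta = fr.loglik + _half_normal_logpdf(np.array([sb]), prior_scale) + theta_beta
        prop_b = theta_beta + step_beta * rng.standard_normal()
        sb_p = math.exp(prop_b)
        fr_p = rw_filter(obs, obs_var=sy2, q=sb_p**2, init_var=sb_p**2)
        lp_b = fr_p.loglik + _half_normal_logpdf(np.array([sb_p]), prior_scale) + prop_b
        accepted_b = np.log(rng.uniform()) < lp_b - ll_beta
        if accepted_b:
            theta_beta, sb, fr = prop_b, sb_p, fr_p
        if it < warmup:
            step_beta = _rw_adapt(step_beta, accepted_b, it)

        # -- beta_common | y, w, sigmas  (FFBS on the shifted observations)
        beta_common = backward_sample(fr, q=sb**2, rng=rng)
        beta_each = _beta_each_matrix(beta_common, inp)
        ll_noise = None  # residuals changed; recompute next iteration

        if it >= warmup:
            k = it - warmup
            out_beta[k] = beta_common
            out_w[k] = w
            out_sigma[k] = (sw, sb, sy)

    alpha = out_w.copy()
    alpha[:, t0_pos:] += out_beta
    return {"beta": out_beta, "alpha": alpha, "w": out_w, "sigma": out_sigma}


def reconstruct_common_distance(
    alpha_draws: np.ndarray,
    grid: TimeGrid,
    levels: Iterable[int] = (95,),
) -> pd.DataFrame:
    """Common distance per draw: cumulative velocity minus its pre-onset sum.

    ``dist[t] = sum(alpha[1..t]) - sum(alpha[1..t0-1])`` for ``t = 1..T``,
    which is exactly zero at ``t = t0 - 1`` in every draw; summarised by the
    per-time median and equal-tailed bounds.
    """
    cum = np.cumsum(alpha_draws, axis=1)
    anchor_pos = grid.onset_velocity_index - 2  # position of t0-1 in 1..T
    if anchor_pos >= 0:
        dist = cum - cum[:, anchor_pos : anchor_pos + 1]
    else:
        dist = cum
    return _quantile_frame(dist, grid.velocity_indices, tuple(sorted(set(int(L) for L in levels))))


def fit_common(
    inp: CommonModelInput,
    spec: Optional[IndividualModelSpec] = None,
    mcmc: McmcConfig = McmcConfig(),
    levels: Iterable[int] = (95,),
) -> CommonDynamics:
    """Posterior of the common dynamics of one cell.

    Requires at least one organelle with a finite start (two or more for a
    meaningful common trajectory).  Non-convergence is flagged on the
    result.
    """
    spec = spec or IndividualModelSpec(grid=inp.grid)
    if spec.grid != inp.grid:
        raise ValueError("spec grid does not match input grid")
    levels = tuple(sorted(set(int(L) for L in levels)))

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [
        _run_common_chain(
            inp, spec.prior_sd_scale, mcmc.warmup, mcmc.samples_per_chain,
            np.random.default_rng(s),
        )
        for s in seeds
    ]
    beta = np.concatenate([c["beta"] for c in chains])
    alpha = np.concatenate([c["alpha"] for c in chains])
    w = np.concatenate([c["w"] for c in chains])
    sigma = np.concatenate([c["sigma"] for c in chains])

    rhat: dict[str, float] = {}
    c, n = mcmc.chains, mcmc.samples_per_chain
    if c >= 2:
        # as in the individual model, only sigma_beta and the total noise SD
        # are identified; monitor those plus a mid-trajectory state
        rhat["sigma_beta"] = _split_rhat(sigma[:, 1].reshape(c, n))
        total = np.sqrt(sigma[:, 0] ** 2 + sigma[:, 2] ** 2)
        rhat["sigma_total"] = _split_rhat(total.reshape(c, n))
        mid = beta.shape[1] // 2
        rhat["beta_mid"] = _split_rhat(beta[:, mid].reshape(c, n))
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = all(v <= mcmc.rhat_threshold for v in finite)

    grid = inp.grid
    dist = reconstruct_common_distance(alpha, grid, levels)
    return CommonDynamics(
        beta=_quantile_frame(beta, grid.beam_velocity_indices, levels),
        alpha=_quantile_frame(alpha, grid.velocity_indices, levels),
        w=_quantile_frame(w, grid.velocity_indices, levels),
        dist=dist,
        sigma={
            "sigma_w": float(np.median(sigma[:, 0])),
            "sigma_beta": float(np.median(sigma[:, 1])),
            "sigma_y": float(np.median(sigma[:, 2])),
        },
        levels=levels,
        grid=grid,
        rhat=rhat,
        converged=converged,
        beta_draws=beta,
        alpha_draws=alpha,
        sigma_draws=sigma,
    )
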