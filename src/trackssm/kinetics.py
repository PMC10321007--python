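"""Per-track summaries, robust regression and kinetic comparisons.

Covers: summarising the fitted stimulus coefficient and velocity per track,
Siegel repeated-median regression (with bootstrap uncertainty), per-cell
signal-transfer speed as the slope of distance-at-onset vs. start time,
signal transfer time, and the one-sided paired comparison of transfer time
against total reaction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from trackssm.ssm_bayes import PosteriorDraws, PosteriorSummary, StartTimeEstimate
from trackssm.trajectories import CellTrack, TimeGrid

__all__ = [
    "TrackSummary",
    "RegressionFit",
    "WilcoxonResult",
    "track_summaries",
    "repeated_median_fit",
    "fit_signal_speed",
    "signal_transfer_time",
    "compare_transfer_vs_total",
]


@dataclass
class TrackSummary:
    """Scalar summaries of one track's fitted dynamics."""

    cell_id: str
    organelle_id: str
    mean_coef: float
    min_coef: float
    sd_coef: float
    mean_vel: float
    min_vel: float
    d_start: float
    start_min: float
    start_finite: bool


@dataclass
class RegressionFit:
    """Repeated-median line fit with bootstrap uncertainty."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool
    method: str  # "exact" or "normal"


def track_summaries(
    summary: PosteriorSummary,
    detector_start: StartTimeEstimate,
    track: CellTrack,
    grid: TimeGrid,
    draws: Optional[PosteriorDraws] = None,
) -> TrackSummary:
    """Collapse a track's posterior summary into the scalars used downstream.

    ``mean_coef``/``min_coef`` are the mean and minimum of the per-time
    medians of the stimulus coefficient over the stimulus period;
    ``sd_coef`` is the median over draws of each draw's across-time SD
    (when draws are available, otherwise the SD of the medians).  Velocity
    summaries are analogous from the velocity-state medians; ``d_start`` is
    the distance at the last pre-stimulus frame.
    """
    beta_medians = summary.beta["median"].to_numpy()
    if draws is not None:
        sd_coef = float(np.median(np.std(draws.beta, axis=1)))
    else:
        sd_coef = float(np.std(beta_medians))
    if summary.alpha is not None:
        alpha_beam = summary.alpha["median"].to_numpy()[grid.onset_velocity_index - 1 :]
    else:
        alpha_beam = beta_medians
    return TrackSummary(
        cell_id=track.cell_id,
        organelle_id=track.organelle_id,
        mean_coef=float(np.mean(beta_medians)),
        min_coef=float(np.min(beta_medians)),
        sd_coef=sd_coef,
        mean_vel=float(np.mean(alpha_beam)),
        min_vel=float(np.min(alpha_beam)),
        d_start=float(track.distances[grid.onset_velocity_index - 1]),
        start_min=detector_start.start_min,
        start_finite=detector_start.is_finite,
    )


def _siegel_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # slope_i = median over j != i of (y_j - y_i)/(x_j - x_i); pairs with
    # equal x are excluded from that inner median.
    dx = x[None, :] - x[:, None]
    dy = y[None, :] - y[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = dy / dx
    per_point = []
    for i in range(len(x)):
        row = slopes[i]
        row = row[np.isfinite(row)]
        if len(row):
            per_point.append(np.median(row))
    slope = float(np.median(per_point))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def repeated_median_fit(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> RegressionFit:
    """Siegel repeated-median regression of *y* on *x*.

    The slope is the median over points of the median of pairwise slopes
    (50% breakdown point).  R^2 is ``1 - SS_res/SS_tot`` evaluated on this
    fit.  The 95% slope CI comes from a seeded case-resampling bootstrap and
    the p-value is the two-sided bootstrap probability that the slope is on
    the other side of zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values")

    slope, intercept = _siegel_slope_intercept(x, y)
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    degenerate = ss_tot == 0.0
    r2 = float("nan") if degenerate else 1.0 - ss_res / ss_tot
    if not degenerate and not (0.0 <= r2 <= 1.0):
        degenerate = True

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    kept = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if len(np.unique(xb)) < 2:
            continue
        boot[kept] = _siegel_slope_intercept(xb, yb)[0]
        kept += 1
    boot = boot[:kept]
    if kept >= 10:
        ci_low, ci_high = np.quantile(boot, [0.025, 0.975])
        p_lower = (np.sum(boot <= 0) + 1) / (kept + 1)
        p_upper = (np.sum(boot >= 0) + 1) / (kept + 1)
        p_value = float(min(1.0, 2.0 * min(p_lower, p_upper)))
    else:
        ci_low = ci_high = slope
        p_value = float("nan")
    ci_low = float(min(ci_low, slope))
    ci_high = float(max(ci_high, slope))
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        ci_low=ci_low,
        ci_high=ci_high,
        r2=r2,
        p_value=p_value,
        n=n,
        degenerate=degenerate,
    )


def fit_signal_speed(
    starts: Sequence[float],
    d_start: Sequence[float],
    cell_id: Optional[str] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> RegressionFit:
    """Signal-transfer speed of a cell (µm/min).

    Repeated-median regression of the distance at stimulus onset (response)
    on the start time of movement (explanatory); the slope is the speed at
    which the triggering signal travels.  Organelles with non-finite start
    times are excluded; at least 3 finite pairs are required.
    """
    starts = np.asarray(starts, dtype=float)
    d_start = np.asarray(d_start, dtype=float)
    keep = np.isfinite(starts) & np.isfinite(d_start)
    if keep.sum() < 3:
        label = f" in cell {cell_id}" if cell_id else ""
        raise ValueError(f"fewer than 3 finite start times{label}")
    return repeated_median_fit(starts[keep], d_start[keep], n_boot=n_boot, seed=seed)


def signal_transfer_time(d_start: float, speed: float) -> float:
    """Minutes for the signal to reach an organelle: distance / speed."""
    if speed <= 0:
        raise ValueError("signal speed must be positive")
    return d_start / speed


def _exact_signed_rank_less(diff: np.ndarray) -> tuple[float, float]:
    """Exact one-sided ('less') Wilcoxon signed-rank p-value.

    Handles ties via midranks: doubling the ranks makes them integers, and
    the null distribution of the positive-rank sum is built by the standard
    shift-algorithm polynomial convolution.
    """
    ranks = stats.rankdata(np.abs(diff))
    w_plus = float(np.sum(ranks[diff > 0]))
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    # counts[k] = number of sign patterns with doubled rank sum k
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p = float(counts[: w2 + 1].sum())
    return w_plus, p


def compare_transfer_vs_total(
    transfer: Sequence[float],
    total: Sequence[float],
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Paired one-sided Wilcoxon signed-rank test (transfer < total).

    Zero differences are dropped.  Up to ``exact_max_n`` non-zero pairs the
    p-value is exact (tie-aware enumeration of the signed-rank
    distribution); above that a normal approximation with tie correction is
    used.
    """
    transfer = np.asarray(transfer, dtype=float)
    total = np.asarray(total, dtype=float)
    if len(transfer) != len(total) or len(transfer) == 0:
        raise ValueError("need equal-length, non-empty paired samples")
    if not (np.all(np.isfinite(transfer)) and np.all(np.isfinite(total))):
        raise ValueError("paired values must be finite")
    diff = transfer - total
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n=0, degenerate=True, method="exact")
    if n <= exact_max_n:
        w_plus, p = _exact_signed_rank_less(diff)
        return WilcoxonResult(statistic=w_plus, p_value=p, n=n, degenerate=False, method="exact")
    res = stats.wilcoxon(diff, alternative="less", method="approx", correction=True)
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        degenerate=False,
        method="normal",
    )
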