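"""Model-free start-time detector on raw distances, plus its grid-search tuner.

The start of directed movement is the first stimulus-on index at which
three criteria hold simultaneously:

1. the distance decreased strictly at each of the last ``k_consec`` steps;
2. the trailing ``ma_window``-point moving average of the one-step distance
   change is negative (short-term approach confirmed over the long term);
3. the distance drop over the next ``horizon`` points exceeds ``fold`` times
   the mean such drop over the whole stimulus period (strong effect).

The mean in criterion 3 is taken per track over all stimulus-on indices
where the look-ahead is defined.  All criteria are scale- and
translation-invariant in the distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from trackssm.ssm_bayes import StartTimeEstimate
from trackssm.trajectories import CellTrack, TimeGrid, TrackSet

__all__ = ["HeuristicParams", "detect_start_heuristic", "grid_search_params"]


@dataclass(frozen=True)
class HeuristicParams:
    k_consec: int = 3
    ma_window: int = 9  # 1/10 of the default 90-min stimulus period
    horizon: int = 13
    fold: float = 1.5

    def __post_init__(self) -> None:
        if min(self.k_consec, self.ma_window, self.horizon) < 1 or self.fold <= 0:
            raise ValueError("all heuristic parameters must be positive")

    def as_tuple(self) -> tuple[int, int, int, float]:
        return (self.k_consec, self.ma_window, self.horizon, self.fold)


def detect_start_heuristic(
    track: CellTrack,
    grid: TimeGrid,
    params: HeuristicParams = HeuristicParams(),
    direction: str = "approach",
) -> StartTimeEstimate:
    """First stimulus-on index meeting all three criteria, or infinity.

    ``direction="escape"`` mirrors every criterion (the distance must
    *increase*); this is implemented by negating the distances, which is
    exact because all three criteria are translation-invariant.
    """
    track.validate_grid(grid)
    if direction not in ("approach", "escape"):
        raise ValueError("direction must be 'approach' or 'escape'")
    if max(params.ma_window, params.horizon) > grid.n_beam:
        raise ValueError("ma_window and horizon must not exceed the stimulus period")
    d = track.distances if direction == "approach" else -track.distances
    T = grid.last_velocity_index
    t0 = grid.onset_velocity_index
    steps = np.diff(d)  # steps[i] is the change ending at frame i+1

    # Criterion 3 baseline: mean look-ahead drop over the stimulus period.
    valid_s = np.arange(t0, T - params.horizon + 1)
    if len(valid_s) == 0:
        return StartTimeEstimate(start_min=math.inf, threshold_used=None, method="heuristic")
    drops = d[valid_s] - d[valid_s + params.horizon]
    mean_drop = float(np.mean(drops))

    for t in range(t0, T + 1):
        # 1: k_consec strictly decreasing steps ending at frame t
        if t - params.k_consec < 0:
            continue
        if not np.all(steps[t - params.k_consec : t] < 0):
            continue
        # 2: trailing moving average of the change is negative
        if t - params.ma_window < 0:
            continue
        if np.mean(steps[t - params.ma_window : t]) >= 0:
            continue
        # 3: look-ahead drop strong relative to the track's mean drop
        if t + params.horizon > T:
            continue
        if not (d[t] - d[t + params.horizon] > params.fold * mean_drop):
            continue
        return StartTimeEstimate(
            start_min=grid.start_min_from_velocity_index(t),
            threshold_used=None,
            method="heuristic",
        )
    return StartTimeEstimate(start_min=math.inf, threshold_used=None, method="heuristic")


def grid_search_params(
    tracks: TrackSet,
    visual: Mapping[tuple[str, str], float],
    grids: Mapping[str, Sequence],
) -> tuple[HeuristicParams, float]:
    """Exhaustive tuning of the detector against visual annotations.

    ``grids`` maps parameter names (``k_consec``, ``ma_window``, ``horizon``,
    ``fold``) to candidate values; omitted parameters keep their defaults.
    RMSE is computed over annotated tracks where both the detector and the
    annotation are finite; a parameter tuple for which the detector returns
    infinity on more than half of the annotated tracks is disqualified.
    Ties break towards the lexicographically smallest parameter tuple.
    """
    defaults = HeuristicParams()
    axes = {
        "k_consec": list(grids.get("k_consec", [defaults.k_consec])),
        "ma_window": list(grids.get("ma_window", [defaults.ma_window])),
        "horizon": list(grids.get("horizon", [defaults.horizon])),
        "fold": list(grids.get("fold", [defaults.fold])),
    }
    if any(len(v) == 0 for v in axes.values()):
        raise ValueError("empty parameter grid")

    annotated = [
        (t, float(visual[t.key]))
        for t in tracks
        if t.key in visual and math.isfinite(visual[t.key])
    ]
    if not annotated:
        raise ValueError("no tracks with finite visual start times")

    best: tuple | None = None
    combos = sorted(itertools.product(*(axes[k] for k in ("k_consec", "ma_window", "horizon", "fold"))))
    for combo in combos:
        params = HeuristicParams(*combo)
        errors = []
        n_inf = 0
        for track, vis in annotated:
            est = detect_start_heuristic(track, tracks.grid, params)
            if est.is_finite:
                errors.append(est.start_min - vis)
            else:
                n_inf += 1
        if n_inf > len(annotated) / 2 or not errors:
            continue
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        key = (rmse, combo)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("every candidate tuple was disqualified (too many infinite starts)")
    rmse, combo = best
    return HeuristicParams(*combo), rmse
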