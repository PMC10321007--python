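"""Synthetic trajectory generator with known ground truth.

Trajectories follow the generative structure the state-space models assume:
a pre-stimulus random walk of the velocity, a stimulus-induced drift that
begins after a distance-dependent lag (distance / signal speed, plus an
optional warm-up), and Gaussian observation error.  The drift shape over
time-since-individual-start is a user-overridable ``beta_profile``
(negative for accumulation towards the stimulus, positive for escape).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from trackssm.trajectories import BeamGeometry, CellTrack, TimeGrid, TrackSet

__all__ = [
    "SimParams",
    "SimTruth",
    "OrganelleTruth",
    "default_accumulation_profile",
    "default_escape_profile",
    "simulate_accumulation",
    "simulate_escape",
    "ESCAPE_GRID",
]

BetaProfile = Callable[[np.ndarray], np.ndarray]

#: 200-min observation with the stimulus ON for the last 70 velocity indices.
ESCAPE_GRID = TimeGrid(n_frames=200, frame_interval=1.0, onset_velocity_index=130)


def default_accumulation_profile(
    depth: float = 0.5,
    ramp_min: float = 5.0,
    recover_after: float = 40.0,
    recover_len: float = 20.0,
) -> BetaProfile:
    """Smooth negative drift pulse.

    Ramps down to ``-depth`` over ``ramp_min`` minutes, stays at the plateau,
    then relaxes back to zero over ``recover_len`` minutes starting
    ``recover_after`` minutes after the individual start.  ``profile(s)`` is
    defined for time-since-start ``s >= 0`` (zero for ``s < 0``).
    """

    def profile(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        ramp = np.clip((s + 1.0) / ramp_min, 0.0, 1.0)
        recovery = np.clip(1.0 - (s - recover_after) / recover_len, 0.0, 1.0)
        out = -depth * ramp * np.where(s >= recover_after, recovery, 1.0)
        return np.where(s >= 0, out, 0.0)

    return profile


def default_escape_profile(
    depth: float = 0.5,
    ramp_min: float = 5.0,
    recover_after: float = 40.0,
    recover_len: float = 20.0,
) -> BetaProfile:
    """Positive mirror of :func:`default_accumulation_profile` (movement away)."""
    base = default_accumulation_profile(depth, ramp_min, recover_after, recover_len)

    def profile(s: np.ndarray) -> np.ndarray:
        return -base(s)

    return profile


@dataclass
class SimParams:
    """Parameters of the trajectory simulator.

    ``initial_distances`` is either a (low, high) µm range sampled uniformly
    per organelle or an explicit per-organelle list (recycled across cells).
    The per-organelle lag before drift starts is
    ``round(initial_distance / signal_speed) + warmup_min`` minutes.
    """

    grid: TimeGrid = field(default_factory=TimeGrid)
    n_cells: int = 1
    organelles_per_cell: int = 5
    initial_distances: Union[tuple[float, float], Sequence[float]] = (3.0, 25.0)
    sigma_w: float = 0.3
    sigma_y: float = 0.3
    signal_speed: float = 0.8
    warmup_min: float = 0.0
    beta_profile: Optional[BetaProfile] = None
    with_xy: bool = False
    beam_geometry: BeamGeometry = field(default_factory=BeamGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_w < 0 or self.sigma_y < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.signal_speed <= 0:
            raise ValueError("signal_speed must be positive")
        if self.n_cells < 1 or self.organelles_per_cell < 1:
            raise ValueError("need at least one cell and one organelle")


@dataclass
class OrganelleTruth:
    cell_id: str
    organelle_id: str
    initial_distance: float
    true_start_min: float
    true_beta: np.ndarray  # over beam-period velocity indices t0..T


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    organelles: list[OrganelleTruth]
    signal_speed: float

    def start_of(self, cell_id: str, organelle_id: str) -> float:
        for o in self.organelles:
            if (o.cell_id, o.organelle_id) == (cell_id, organelle_id):
                return o.true_start_min
        raise KeyError((cell_id, organelle_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": [o.cell_id for o in self.organelles],
                "organelle": [o.organelle_id for o in self.organelles],
                "initial_distance_um": [o.initial_distance for o in self.organelles],
                "true_start_min": [o.true_start_min for o in self.organelles],
                "signal_speed": self.signal_speed,
            }
        )


def _organelle_seeds(seed: int, n_cells: int, n_org: int) -> list[list[np.random.SeedSequence]]:
    # One substream per organelle, derived deterministically from the run seed,
    # so adding organelles/cells never perturbs earlier ones.
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_cells)
    return [cs.spawn(n_org) for cs in streams]


def _simulate(params: SimParams, profile: BetaProfile, escape: bool) -> tuple[TrackSet, SimTruth]:
    grid = params.grid
    T = grid.last_velocity_index
    t0 = grid.onset_velocity_index
    t_vel = grid.velocity_indices  # 1..T

    seeds = _organelle_seeds(params.seed, params.n_cells, params.organelles_per_cell)
    explicit = not (
        isinstance(params.initial_distances, tuple) and len(params.initial_distances) == 2
        and all(np.isscalar(v) for v in params.initial_distances)
    )
    if explicit:
        d0_list = list(params.initial_distances)

    tracks: list[CellTrack] = []
    truths: list[OrganelleTruth] = []
    n_floored_tracks = 0
    for ci in range(params.n_cells):
        cell_id = f"cell{ci + 1}"
        for oi in range(params.organelles_per_cell):
            organelle_id = f"org{oi + 1}"
            rng = np.random.default_rng(seeds[ci][oi])
            if explicit:
                d0 = float(d0_list[oi % len(d0_list)])
            else:
                lo, hi = params.initial_distances
                d0 = float(rng.uniform(lo, hi))
            lag = round(d0 / params.signal_speed) + params.warmup_min
            start_min = float(lag)
            t_star = t0 - 1 + int(round(lag / grid.frame_interval))  # first drifting index

            beta_each = profile((t_vel - t_star).astype(float))
            beta_each = np.where(t_vel >= max(t_star, t0), beta_each, 0.0)
            w = rng.normal(0.0, params.sigma_w, size=T)
            eps = rng.normal(0.0, params.sigma_y, size=T)
            y = w + beta_each + eps
            distances = d0 + np.concatenate([[0.0], np.cumsum(y)])
            # an organelle cannot be nearer than the stimulus edge; distances
            # are floored at zero in both response modes (unbounded above)
            floored = distances < 0
            if floored.sum() > len(distances) / 2:
                n_floored_tracks += 1
            distances = np.maximum(distances, 0.0)

            xy = None
            if params.with_xy:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                centre = np.asarray(params.beam_geometry.centre)
                radial = params.beam_geometry.beam_radius + distances
                xy = centre + np.outer(radial, [np.cos(theta), np.sin(theta)])

            tracks.append(
                CellTrack(cell_id=cell_id, organelle_id=organelle_id, distances=distances, xy=xy)
            )
            truths.append(
                OrganelleTruth(
                    cell_id=cell_id,
                    organelle_id=organelle_id,
                    initial_distance=d0,
                    true_start_min=start_min,
                    true_beta=beta_each[t0 - 1 :],
                )
            )
    if n_floored_tracks:
        warnings.warn(
            f"{n_floored_tracks} track(s) had a majority of frames floored at distance 0; "
            "the drift profile may be too deep for the initial distances",
            stacklevel=3,
        )
    trackset = TrackSet(
        grid=grid,
        tracks=tracks,
        beam_geometry=params.beam_geometry if params.with_xy else None,
    )
    return trackset, SimTruth(organelles=truths, signal_speed=params.signal_speed)


def simulate_accumulation(params: SimParams) -> tuple[TrackSet, SimTruth]:
    """Simulate accumulation-response trajectories (drift towards the stimulus).

    The velocity at index ``t`` is ``w[t] + beta_each[t] + eps[t]`` with
    ``w ~ N(0, sigma_w^2)``, ``eps ~ N(0, sigma_y^2)`` and ``beta_each`` the
    drift profile shifted so it switches on at the organelle's own start
    index.  Distances are the cumulative sum floored at zero (an organelle
    cannot be nearer than the stimulus edge); identical seeds give identical
    output.
    """
    profile = params.beta_profile or default_accumulation_profile()
    return _simulate(params, profile, escape=False)


def simulate_escape(params: SimParams) -> tuple[TrackSet, SimTruth]:
    """Simulate escape-response trajectories (drift away from the stimulus).

    Same generative scheme as :func:`simulate_accumulation` with a positive
    drift profile and no upper bound on distance.  Pair with
    :data:`ESCAPE_GRID` (200-min series, 70-min stimulus window) for the
    default escape scenario.
    """
    profile = params.beta_profile or default_escape_profile()
    return _simulate(params, profile, escape=True)
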