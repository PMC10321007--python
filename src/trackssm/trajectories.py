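"""Data model, validation and I/O for tracked movement time series.

Indexing conventions used throughout the package:

- Distance frames are indexed ``0..T`` (``T = n_frames - 1``); ``distances[k]``
  is the distance (µm) of the organelle centre from the stimulus edge at
  frame ``k``.
- Velocity indices run ``1..T``; velocity ``y[t] = d[t] - d[t-1]`` refers to
  the step *ending* at frame ``t`` and is stored at array position ``t - 1``.
- The stimulus indicator is 0 for ``t < t0`` and 1 for ``t >= t0`` where
  ``t0`` is the first stimulus-on velocity index.
- The "distance at stimulus onset" used downstream is ``distances[t0 - 1]``,
  the last pre-stimulus frame.
- Start times are reported in minutes after stimulus onset:
  ``start_min = t* - (t0 - 1)`` for the first qualifying velocity index
  ``t*`` (an immediate response is 1 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "CellTrack",
    "TrackSet",
    "VelocitySeries",
    "BeamGeometry",
    "TrackValidationError",
    "beam_indicator",
    "compute_velocity",
    "load_tracks",
    "write_tracks",
]


class TrackValidationError(ValueError):
    """Raised when an input trajectory table violates the data contract."""


@dataclass(frozen=True)
class TimeGrid:
    """Shared time grid for a set of tracks.

    Parameters
    ----------
    n_frames
        Number of distance frames (default 120, i.e. frames ``0..119``).
    frame_interval
        Minutes between frames (default 1).
    onset_velocity_index
        First velocity index ``t0`` with the stimulus ON (default 30).
    """

    n_frames: int = 120
    frame_interval: float = 1.0
    onset_velocity_index: int = 30

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (1 <= self.onset_velocity_index <= self.last_velocity_index):
            raise ValueError(
                f"onset_velocity_index must be in [1, {self.last_velocity_index}], "
                f"got {self.onset_velocity_index}"
            )

    @property
    def last_velocity_index(self) -> int:
        """T, the last velocity index (= n_frames - 1)."""
        return self.n_frames - 1

    @property
    def t0(self) -> int:
        """Alias for :attr:`onset_velocity_index`."""
        return self.onset_velocity_index

    @property
    def n_velocity(self) -> int:
        """Number of velocity indices (1..T)."""
        return self.n_frames - 1

    @property
    def n_beam(self) -> int:
        """Number of stimulus-on velocity indices (t0..T)."""
        return self.last_velocity_index - self.onset_velocity_index + 1

    @property
    def beam_velocity_indices(self) -> np.ndarray:
        """Velocity indices with the stimulus ON, ``t0..T``."""
        return np.arange(self.onset_velocity_index, self.last_velocity_index + 1)

    @property
    def velocity_indices(self) -> np.ndarray:
        """All velocity indices, ``1..T``."""
        return np.arange(1, self.last_velocity_index + 1)

    def start_min_from_velocity_index(self, t_star: int) -> float:
        """Minutes after stimulus onset for a first-qualifying velocity index."""
        return (t_star - (self.onset_velocity_index - 1)) * self.frame_interval

    def velocity_index_from_start_min(self, start_min: float) -> int:
        """Inverse of :meth:`start_min_from_velocity_index`."""
        return int(round(start_min / self.frame_interval)) + self.onset_velocity_index - 1


@dataclass(frozen=True)
class BeamGeometry:
    """Optional stimulus geometry (for pairwise alignment judgements)."""

    centre: tuple[float, float] = (0.0, 0.0)
    beam_radius: float = 5.0
    organelle_radius: float = 2.5


@dataclass
class CellTrack:
    """Distance time series of one organelle in one cell."""

    cell_id: str
    organelle_id: str
    distances: np.ndarray
    xy: Optional[np.ndarray] = None
    visual_start: Optional[float] = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1:
            raise TrackValidationError(
                f"({self.cell_id}, {self.organelle_id}): distances must be 1-D"
            )
        if not np.all(np.isfinite(self.distances)):
            raise TrackValidationError(
                f"({self.cell_id}, {self.organelle_id}): non-finite distance"
            )
        if np.any(self.distances < 0):
            raise TrackValidationError(
                f"({self.cell_id}, {self.organelle_id}): negative distance"
            )
        if self.xy is not None:
            self.xy = np.asarray(self.xy, dtype=float)
            if self.xy.shape != (len(self.distances), 2):
                raise TrackValidationError(
                    f"({self.cell_id}, {self.organelle_id}): xy shape "
                    f"{self.xy.shape} does not match {len(self.distances)} frames"
                )

    def validate_grid(self, grid: TimeGrid) -> None:
        if len(self.distances) != grid.n_frames:
            raise TrackValidationError(
                f"({self.cell_id}, {self.organelle_id}): {len(self.distances)} frames, "
                f"expected {grid.n_frames}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.cell_id, self.organelle_id)


@dataclass
class TrackSet:
    """A collection of tracks sharing one :class:`TimeGrid`."""

    grid: TimeGrid
    tracks: list[CellTrack] = field(default_factory=list)
    beam_geometry: Optional[BeamGeometry] = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for track in self.tracks:
            track.validate_grid(self.grid)
            if track.key in seen:
                raise TrackValidationError(f"duplicate track {track.key}")
            seen.add(track.key)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def cell_ids(self) -> list[str]:
        out: list[str] = []
        for track in self.tracks:
            if track.cell_id not in out:
                out.append(track.cell_id)
        return out

    def cell(self, cell_id: str) -> list[CellTrack]:
        return [t for t in self.tracks if t.cell_id == cell_id]

    def get(self, cell_id: str, organelle_id: str) -> CellTrack:
        for t in self.tracks:
            if t.key == (cell_id, organelle_id):
                return t
        raise KeyError((cell_id, organelle_id))


@dataclass
class VelocitySeries:
    """First differences of a track, paired with the stimulus indicator.

    ``y[i]`` holds the velocity at index ``t = i + 1`` (µm/min);
    ``beam`` is the 0/1 stimulus indicator aligned the same way.
    """

    y: np.ndarray
    beam: np.ndarray
    grid: TimeGrid
    d0: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.beam = np.asarray(self.beam, dtype=float)
        if len(self.y) != self.grid.n_velocity or len(self.beam) != self.grid.n_velocity:
            raise ValueError("velocity/beam length does not match grid")


def beam_indicator(grid: TimeGrid) -> np.ndarray:
    """0/1 stimulus indicator over velocity indices 1..T.

    Zero for ``1 <= t <= t0 - 1`` and one for ``t0 <= t <= T``; with the
    default grid this is 29 zeros followed by 90 ones.
    """
    t = grid.velocity_indices
    return (t >= grid.onset_velocity_index).astype(float)


def compute_velocity(track: CellTrack, grid: TimeGrid) -> VelocitySeries:
    """First-difference a track: ``y[t] = d[t] - d[t-1]`` for ``t = 1..T``.

    Negative velocity means the organelle approaches the stimulus.  The
    cumulative sum of ``y`` plus ``d[0]`` reproduces the distances exactly.
    """
    track.validate_grid(grid)
    y = np.diff(track.distances)
    return VelocitySeries(y=y, beam=beam_indicator(grid), grid=grid, d0=float(track.distances[0]))


_REQUIRED_COLUMNS = ("cell", "organelle", "time_min", "distance_um")
_OPTIONAL_COLUMNS = ("x_um", "y_um", "visual_start_min")


def load_tracks(path: Union[str, Path], grid: TimeGrid) -> TrackSet:
    """Read a trajectory table from CSV and validate it against *grid*.

    The CSV must have columns ``cell, organelle, time_min, distance_um``
    (optionally ``x_um, y_um, visual_start_min``) with exactly one row per
    frame per (cell, organelle).  Missing frames, duplicate rows or
    non-numeric distances are rejected with a message naming the offending
    (cell, organelle, time).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(f"{path}: missing required columns {missing}")

    expected_times = np.arange(grid.n_frames) * grid.frame_interval
    has_xy = "x_um" in df.columns and "y_um" in df.columns
    has_visual = "visual_start_min" in df.columns

    tracks: list[CellTrack] = []
    for (cell, organelle), sub in df.groupby(["cell", "organelle"], sort=True):
        cell, organelle = str(cell), str(organelle)
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(dtype=float)
        if len(times) != grid.n_frames or not np.allclose(times, expected_times):
            dup = sub["time_min"][sub["time_min"].duplicated()]
            if len(dup):
                raise TrackValidationError(
                    f"({cell}, {organelle}): duplicate rows at time {dup.iloc[0]}"
                )
            present = set(np.round(times / grid.frame_interval).astype(int))
            missing_frames = [
                f * grid.frame_interval for f in range(grid.n_frames) if f not in present
            ]
            if missing_frames:
                raise TrackValidationError(
                    f"({cell}, {organelle}): missing frame at time {missing_frames[0]}"
                )
            raise TrackValidationError(
                f"({cell}, {organelle}): time grid does not match "
                f"{grid.n_frames} frames at {grid.frame_interval} min"
            )
        dist_raw = pd.to_numeric(sub["distance_um"], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(dist_raw))
        if len(bad):
            raise TrackValidationError(
                f"({cell}, {organelle}): non-numeric distance at time {times[bad[0]]}"
            )
        xy = None
        if has_xy:
            xy_raw = sub[["x_um", "y_um"]].apply(pd.to_numeric, errors="coerce").to_numpy()
            if np.all(np.isfinite(xy_raw)):
                xy = xy_raw
        visual = None
        if has_visual:
            v = pd.to_numeric(sub["visual_start_min"], errors="coerce").iloc[0]
            if np.isfinite(v):
                visual = float(v)
        tracks.append(
            CellTrack(
                cell_id=cell,
                organelle_id=organelle,
                distances=dist_raw,
                xy=xy,
                visual_start=visual,
            )
        )
    return TrackSet(grid=grid, tracks=tracks)


def write_tracks(trackset: TrackSet, path: Union[str, Path]) -> None:
    """Write a :class:`TrackSet` back to the CSV schema read by :func:`load_tracks`."""
    grid = trackset.grid
    times = np.arange(grid.n_frames) * grid.frame_interval
    any_xy = any(t.xy is not None for t in trackset.tracks)
    any_visual = any(t.visual_start is not None for t in trackset.tracks)
    rows = []
    for track in trackset.tracks:
        for k in range(grid.n_frames):
            row = {
                "cell": track.cell_id,
                "organelle": track.organelle_id,
                "time_min": times[k],
                "distance_um": track.distances[k],
            }
            if any_xy:
                row["x_um"] = track.xy[k, 0] if track.xy is not None else math.nan
                row["y_um"] = track.xy[k, 1] if track.xy is not None else math.nan
            if any_visual:
                row["visual_start_min"] = (
                    track.visual_start if track.visual_start is not None else math.nan
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
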