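"""Pairwise signal-transfer speeds, alignment geometry and contingency test.

For every unordered pair of organelles with finite start times in a cell,
the pairwise transfer speed is the distance gap at stimulus onset divided by
the start-time gap.  A negative speed means the farther organelle responded
first.  A pair is "aligned" when the nearer organelle sits on the segment
from the stimulus centre to the farther organelle's centre (within one
organelle radius).  Alignment and speed sign are cross-tabulated and tested
with Fisher's exact test (two-sided).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairEntry",
    "PairComparison",
    "pairwise_speeds",
    "judge_alignment",
    "alignment_contingency_fisher",
]


@dataclass(frozen=True)
class PairEntry:
    """Per-organelle inputs to the pairwise analysis."""

    organelle_id: str
    d_start: float
    start_min: float
    xy_at_onset: Optional[tuple[float, float]] = None


@dataclass
class PairComparison:
    """One organelle pair; ``a`` is the nearer organelle at stimulus onset."""

    organelle_a: str
    organelle_b: str
    delta_d: float  # d_b - d_a >= 0
    delta_start: float  # start_b - start_a
    speed: Optional[float]  # µm/min; None when delta_start == 0
    aligned: Optional[bool]  # None when coordinates are missing
    sign: Optional[str]  # "positive" / "negative"; None when speed undefined


def judge_alignment(
    near_xy: Sequence[float],
    far_xy: Sequence[float],
    beam_centre: Sequence[float],
    organelle_radius: float,
) -> bool:
    """Is the nearer organelle on the stimulus-centre -> farther-organelle line?

    True when the perpendicular distance from the nearer organelle's centre
    to the segment from the stimulus centre to the farther organelle's
    centre is at most one organelle radius and its projection falls within
    the segment.
    """
    p = np.asarray(near_xy, dtype=float)
    a = np.asarray(beam_centre, dtype=float)
    b = np.asarray(far_xy, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return bool(np.linalg.norm(p - a) <= organelle_radius)
    s = float((p - a) @ ab) / denom
    if not (0.0 <= s <= 1.0):
        return False
    perp = float(np.linalg.norm(p - (a + s * ab)))
    return perp <= organelle_radius


def pairwise_speeds(
    entries: Sequence[PairEntry],
    beam_centre: Optional[Sequence[float]] = None,
    organelle_radius: Optional[float] = None,
) -> list[PairComparison]:
    """All unordered pairs among organelles with finite start times.

    Ties in onset distance are broken by organelle label so the nearer
    member is well-defined; pairs with equal start times have an undefined
    speed and are excluded from downstream sign counts.  Alignment is
    judged when coordinates and geometry are available, otherwise left
    unknown.
    """
    finite = [e for e in entries if math.isfinite(e.start_min)]
    if len(finite) < 2:
        raise ValueError("need at least 2 organelles with finite start times")
    pairs: list[PairComparison] = []
    for e1, e2 in itertools.combinations(finite, 2):
        near, far = sorted([e1, e2], key=lambda e: (e.d_start, e.organelle_id))
        delta_d = far.d_start - near.d_start
        delta_start = far.start_min - near.start_min
        if delta_start == 0.0:
            speed = None
            sign = None
        else:
            speed = delta_d / delta_start
            sign = "positive" if speed >= 0 else "negative"
        aligned: Optional[bool] = None
        if (
            beam_centre is not None
            and organelle_radius is not None
            and near.xy_at_onset is not None
            and far.xy_at_onset is not None
        ):
            aligned = judge_alignment(near.xy_at_onset, far.xy_at_onset, beam_centre, organelle_radius)
        pairs.append(
            PairComparison(
                organelle_a=near.organelle_id,
                organelle_b=far.organelle_id,
                delta_d=delta_d,
                delta_start=delta_start,
                speed=speed,
                aligned=aligned,
                sign=sign,
            )
        )
    return pairs


def alignment_contingency_fisher(
    pairs: Sequence[PairComparison],
) -> tuple[np.ndarray, float]:
    """2x2 table (rows aligned/not-aligned, columns positive/negative) + p.

    Pairs with unknown alignment or undefined speed are excluded.  The
    two-sided p-value sums hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    """
    table = np.zeros((2, 2), dtype=int)
    for pair in pairs:
        if pair.aligned is None or pair.sign is None:
            continue
        row = 0 if pair.aligned else 1
        col = 0 if pair.sign == "positive" else 1
        table[row, col] += 1
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"empty margin in contingency table {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
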