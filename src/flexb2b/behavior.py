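"""Trajectory quantification: heading, displacements, turns, statistics.

Heading is taken from the velocity direction ``atan2(dy, dx)`` and
unwrapped, with a minimum-motion threshold below which the last heading is
held (heading is undefined while the animal is stationary).  Leftward
(counterclockwise) turning is positive angular displacement; a valid turn
is one whose absolute angle exceeds 20 degrees.  "Linear displacement" is
accumulated path length, not net displacement.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .evaluate import ConfusionMatrix
from .synth import COMMANDS, Trajectory

__all__ = [
    "TURN_THRESHOLD_DEG",
    "heading_series",
    "angular_displacement",
    "linear_displacement",
    "max_angular_change",
    "classify_turn",
    "behavior_confusion",
    "compare_phases",
]

#: Valid-turn threshold: |angle| must exceed this many degrees.
TURN_THRESHOLD_DEG = 20.0

#: Steps shorter than this (mm) do not update the heading.
MIN_MOTION_MM = 1.0


def heading_series(traj: Trajectory,
                   min_motion: float = MIN_MOTION_MM) -> np.ndarray:
    """Unwrapped per-sample heading in degrees.

    Sample ``i`` (i >= 1) carries the direction of the step into it when
    that step exceeds ``min_motion``; otherwise the previous heading is
    held.  Samples before the first supra-threshold step are backfilled
    with the first defined heading (0 if the animal never moves).
    """
    if len(traj.t) < 2:
        raise ValueError("need at least two samples for a heading")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    step = np.hypot(dx, dy)
    moving = step > min_motion
    raw = np.arctan2(dy, dx)
    if not moving.any():
        return np.zeros(len(traj.t))
    # unwrap over moving steps only, hold the last heading between them
    ang = np.full(len(traj.t), np.nan)
    ang[1:][moving] = np.unwrap(raw[moving])
    first = 1 + int(np.argmax(moving))
    ang[:first] = ang[first]  # backfill before first motion
    idx = np.arange(len(ang))
    have = ~np.isnan(ang)
    ang = ang[np.maximum.accumulate(np.where(have, idx, 0))]
    return np.degrees(ang)


def _window_indices(traj: Trajectory, window: tuple[float, float]):
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    sel = (traj.t >= t0) & (traj.t <= t1)
    if not sel.any():
        raise ValueError("window contains no samples")
    return np.flatnonzero(sel)


def angular_displacement(traj: Trajectory, window: tuple[float, float],
                         min_motion: float = MIN_MOTION_MM) -> float:
    """Cumulative signed heading change (deg) over a time window.

    Counterclockwise positive.  Mirroring the trajectory about the x-axis
    negates the result exactly.
    """
    h = heading_series(traj, min_motion)
    ii = _window_indices(traj, window)
    return float(h[ii[-1]] - h[ii[0]])


def linear_displacement(traj: Trajectory,
                        window: tuple[float, float]) -> float:
    """Path length (mm) over a time window: sum of step lengths."""
    ii = _window_indices(traj, window)
    if len(ii) < 2:
        return 0.0
    return float(np.hypot(np.diff(traj.x[ii]), np.diff(traj.y[ii])).sum())


def max_angular_change(traj: Trajectory,
                       phases: dict[str, tuple[float, float]],
                       min_motion: float = MIN_MOTION_MM,
                       endpoint: bool = False) -> dict[str, float]:
    """Per-phase signed heading change of maximum magnitude.

    For each phase window the heading change is accumulated from the phase
    start; the value reported is the extremum (largest |change|) within
    the phase, signed — a transient peak counts even if the animal turns
    back.  ``endpoint=True`` reports the end-of-phase value instead.
    """
    h = heading_series(traj, min_motion)
    out = {}
    for name, window in phases.items():
        ii = _window_indices(traj, window)
        rel = h[ii] - h[ii[0]]
        if endpoint:
            out[name] = float(rel[-1])
        else:
            out[name] = float(rel[np.argmax(np.abs(rel))])
    return out


def classify_turn(angle_deg: float,
                  threshold: float = TURN_THRESHOLD_DEG) -> str:
    """'L' if angle > +threshold, 'R' if < -threshold, else 'X' (strict)."""
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    if angle_deg > threshold:
        return "L"
    if angle_deg < -threshold:
        return "R"
    return "X"


def behavior_confusion(true_commands: list[str],
                       observed_pairs: list[str]) -> ConfusionMatrix:
    """Turning-control confusion: 8 true commands x (8 commands + 'XX').

    'XX' labels trials where neither mouse produced a valid turn; it can
    be observed but never commanded (it corresponds to no stimulation).
    """
    cols = list(COMMANDS) + ["XX"]
    if len(true_commands) != len(observed_pairs):
        raise ValueError("label lists must have equal length")
    for c in true_commands:
        if c not in COMMANDS:
            raise ValueError(f"unknown command {c!r}")
    for c in observed_pairs:
        if c not in cols:
            raise ValueError(f"unknown observed pattern {c!r}")
    counts = np.zeros((len(COMMANDS), len(cols)), dtype=int)
    for t, o in zip(true_commands, observed_pairs):
        counts[COMMANDS.index(t), cols.index(o)] += 1
    return ConfusionMatrix(counts, class_names=list(COMMANDS),
                           pred_names=cols)


_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for level, stars in _STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


def compare_phases(group_a, group_b, welch: bool = False):
    """Two-tailed unpaired Student's t-test between two phases.

    Returns ``(t, p, stars)`` with the conventional star coding
    (ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001).  Pooled
    variance by default, Welch by flag.  Two constant equal groups give
    p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "ns"
        return np.inf, 0.0, "****"
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), significance_stars(float(p))
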