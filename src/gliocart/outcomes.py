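"""Trajectory endpoints: time to progression, threshold crossings, burdens.

Time to progression (TTP) is the number of days until the tumor regrows to
its pre-treatment size, i.e. the first upward crossing of the baseline after
the tumor has first dropped below it.  A tumor that never regresses has
TTP = 0; one that has not yet returned to baseline at the end of the horizon
is censored (reported as ``None``).

Crossings are located by linear interpolation between grid points; at the
default integration step (0.01 day) sub-step root polishing is unnecessary.
The clinical monitoring thresholds used throughout are a tumor burden of
3.5e10 cells (a ~1 cm radius lesion, one third of the lethal burden) and a
CAR-T detectability limit of 1000 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .integrators import Trajectory

__all__ = [
    "Endpoint",
    "TUMOR_CRITICAL_THRESHOLD",
    "CART_DETECTABILITY_THRESHOLD",
    "time_to_progression",
    "first_time_above",
    "first_time_below",
    "value_at",
    "peak_time",
    "max_value",
    "evaluate_endpoint",
]

#: tumor burden of a ~1 cm radius glioblastoma, cells
TUMOR_CRITICAL_THRESHOLD = 3.5e10

#: CAR-T population below which the cells are clinically undetectable
CART_DETECTABILITY_THRESHOLD = 1000.0

_KINDS = ("TTP", "first_above", "first_below", "value_at", "peak_time", "max_value")


@dataclass(frozen=True)
class Endpoint:
    """Declarative endpoint: what to measure on which trajectory variable."""

    kind: str
    variable: str = "T"
    threshold: Optional[float] = None  # crossing endpoints, and TTP baseline
    day: Optional[float] = None        # value_at

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown endpoint kind {self.kind!r}")
        if self.kind in ("first_above", "first_below") and (
            self.threshold is None or self.threshold <= 0
        ):
            raise ValueError("crossing endpoints require a positive threshold")
        if self.kind == "value_at" and self.day is None:
            raise ValueError("value_at requires a day")


def _require_nonempty(traj: Trajectory) -> None:
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def time_to_progression(traj: Trajectory, baseline: Optional[float] = None) -> Optional[float]:
    """Days until the tumor regrows to ``baseline`` (default: T at time 0).

    Returns 0.0 if the tumor never drops below baseline, and ``None``
    (censored) if it drops but has not returned within the horizon.
    """
    _require_nonempty(traj)
    if baseline is None:
        baseline = float(traj.T[0])
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    T, t = traj.T, traj.times
    below = T < baseline
    if not below.any():
        return 0.0
    i0 = int(np.argmax(below))
    up = np.nonzero((T[:-1] < baseline) & (T[1:] >= baseline))[0]
    up = up[up >= i0]
    if len(up) == 0:
        return None
    i = int(up[0])
    return float(_interp_crossing(t[i], t[i + 1], T[i], T[i + 1], baseline))


def first_time_above(traj: Trajectory, variable: str, threshold: float) -> Optional[float]:
    """First time the series reaches or exceeds ``threshold`` (interpolated).

    Returns the start time if the series already begins at or above the
    threshold, and ``None`` if the threshold is never reached.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    _require_nonempty(traj)
    y, t = traj.series(variable), traj.times
    if y[0] >= threshold:
        return float(t[0])
    up = np.nonzero((y[:-1] < threshold) & (y[1:] >= threshold))[0]
    if len(up) == 0:
        return None
    i = int(up[0])
    return float(_interp_crossing(t[i], t[i + 1], y[i], y[i + 1], threshold))


def first_time_below(traj: Trajectory, variable: str, threshold: float) -> Optional[float]:
    """First downward crossing of ``threshold`` (interpolated).

    The series must start at or above the threshold; returns ``None`` if it
    never drops below it within the horizon.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    _require_nonempty(traj)
    y, t = traj.series(variable), traj.times
    if y[0] < threshold:
        raise ValueError("series starts below the threshold")
    dn = np.nonzero((y[:-1] >= threshold) & (y[1:] < threshold))[0]
    if len(dn) == 0:
        return None
    i = int(dn[0])
    return float(_interp_crossing(t[i], t[i + 1], y[i], y[i + 1], threshold))


def value_at(traj: Trajectory, variable: str, day: float) -> float:
    """Linearly interpolated series value at ``day`` (no extrapolation)."""
    _require_nonempty(traj)
    t = traj.times
    if not t[0] <= day <= t[-1]:
        raise ValueError(f"day {day} outside the trajectory span [{t[0]}, {t[-1]}]")
    return float(np.interp(day, t, traj.series(variable)))


def peak_time(traj: Trajectory, variable: str) -> float:
    """Grid time of the global maximum (earliest when tied)."""
    _require_nonempty(traj)
    return float(traj.times[int(np.argmax(traj.series(variable)))])


def max_value(traj: Trajectory, variable: str) -> float:
    """Global maximum of the series."""
    _require_nonempty(traj)
    return float(np.max(traj.series(variable)))


def evaluate_endpoint(traj: Trajectory, ep: Endpoint) -> dict:
    """Evaluate an :class:`Endpoint`, returning ``{value, censored}``."""
    if ep.kind == "TTP":
        v = time_to_progression(traj, ep.threshold)
    elif ep.kind == "first_above":
        v = first_time_above(traj, ep.variable, ep.threshold)
    elif ep.kind == "first_below":
        v = first_time_below(traj, ep.variable, ep.threshold)
    elif ep.kind == "value_at":
        v = value_at(traj, ep.variable, ep.day)
    elif ep.kind == "peak_time":
        v = peak_time(traj, ep.variable)
    else:
        v = max_value(traj, ep.variable)
    return {"value": v, "censored": v is None}
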