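"""Fixed-step integration of the tumor--CAR-T models with impulsive dosing.

The ODE models (base, resistance) are integrated with the classical 4th-order
Runge-Kutta scheme; the delayed-activation model with a 2nd-order Runge-Kutta
(Heun) scheme via the method of steps, looking the lagged term up from the
stored solution.  Cyclic CAR-T administration is represented by impulses: at
each scheduled time the left limit of C is incremented by the dose,

    C(t_n) = lim_{t -> t_n^-} C(t) + m,

while T (and R) carry over continuously.  Trajectories store the
post-impulse (right-continuous) value at dose times and record those times
so that downstream interpolation can respect the discontinuities.

Dose times must lie exactly on the integration grid (whole-day protocol
times do, at the default dt = 0.01 day); off-grid times are rejected rather
than silently rounded.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .dynamics import ModelParams

__all__ = ["DoseSchedule", "Trajectory", "integrate_ode", "integrate_dde"]

#: relative clamp window for small negative populations (solver noise)
_NEG_CLAMP = 1e-9


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered impulsive CAR-T administrations as (time in days, cells).

    Times must be strictly increasing and nonnegative, doses strictly
    positive.  An entry at time 0 seeds the initial condition C(0); without
    one the run starts from C(0) = 0.
    """

    entries: tuple[tuple[float, float], ...]

    def __init__(self, entries: Iterable[Sequence[float]]):
        raw = [(float(t), float(m)) for t, m in entries]
        if any(t < 0 for t, _ in raw):
            raise ValueError("dose times must be >= 0")
        if any(m <= 0 for _, m in raw):
            raise ValueError("doses must be positive")
        # simultaneous administrations are additive: merge exact duplicates
        merged: list[tuple[float, float]] = []
        for t, m in raw:
            if merged and t == merged[-1][0]:
                merged[-1] = (t, merged[-1][1] + m)
            else:
                merged.append((t, m))
        times = [t for t, _ in merged]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        object.__setattr__(self, "entries", tuple(merged))

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])

    @property
    def doses(self) -> np.ndarray:
        return np.array([m for _, m in self.entries])

    @property
    def initial_dose(self) -> float:
        """Dose administered at t = 0, or 0.0 if none is scheduled."""
        return self.entries[0][1] if self.entries and self.entries[0][0] == 0.0 else 0.0

    @property
    def total(self) -> float:
        return float(sum(m for _, m in self.entries))

    def last_time(self) -> float:
        return self.entries[-1][0] if self.entries else 0.0

    def shifted(self, delta: float) -> "DoseSchedule":
        return DoseSchedule([(t + delta, m) for t, m in self.entries])

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["day", "cells"])
            for t, m in self.entries:
                w.writerow([f"{t:.10g}", f"{m:.10g}"])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DoseSchedule":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls([(float(r["day"]), float(r["cells"])) for r in rows])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Trajectory:
    """Integrated solution on a fixed time grid.

    At recorded jump times the stored value is the post-impulse (right)
    limit; the left limit is recoverable from the preceding grid point.
    """

    times: np.ndarray
    T: np.ndarray
    C: np.ndarray
    R: Optional[np.ndarray] = None
    jump_times: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.T) != n or len(self.C) != n:
            raise ValueError("series lengths must equal the grid length")
        if self.R is not None and len(self.R) != n:
            raise ValueError("series lengths must equal the grid length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def series(self, variable: str) -> np.ndarray:
        if variable == "T":
            return self.T
        if variable == "C":
            return self.C
        if variable == "R":
            if self.R is None:
                raise KeyError("trajectory has no resistance series")
            return self.R
        raise KeyError(f"unknown variable {variable!r}")

    def to_csv(self, path: Union[str, Path], sidecar: bool = True) -> None:
        """Write `time,T,C[,R]` CSV; optionally a `.meta.json` sidecar."""
        path = Path(path)
        cols = [("time", self.times), ("T", self.T), ("C", self.C)]
        if self.R is not None:
            cols.append(("R", self.R))
        with open(path, "w", newline="") as fh:
            fh.write(",".join(name for name, _ in cols) + "\n")
            data = np.column_stack([arr for _, arr in cols])
            for row in data:
                fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
        if sidecar:
            meta = dict(self.meta)
            meta["jump_times"] = list(self.jump_times)
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, default=str)
            )


def _grid_index(t: float, dt: float, what: str) -> int:
    """Index of an on-grid time; rejects off-grid times (no silent rounding)."""
    k = round(t / dt)
    if not math.isclose(k * dt, t, rel_tol=0.0, abs_tol=1e-9 * max(1.0, abs(t))):
        raise ValueError(f"{what} {t} is not a multiple of dt={dt}")
    return int(k)


def _dose_steps(schedule: DoseSchedule, dt: float, n_steps: int) -> dict[int, float]:
    out: dict[int, float] = {}
    for t, m in schedule.entries:
        k = _grid_index(t, dt, "dose time")
        if k > n_steps:
            raise ValueError(f"dose time {t} exceeds t_end")
        out[k] = out.get(k, 0.0) + m
    return out


def _guard(value: float, scale: float, name: str, t: float) -> float:
    """Clamp solver-noise negatives; abort on anything larger or non-finite."""
    if value >= 0.0:
        if math.isfinite(value):
            return value
        raise FloatingPointError(f"{name} became non-finite at t={t:.4g}")
    if value > -_NEG_CLAMP * scale:
        return 0.0
    raise FloatingPointError(
        f"{name} became negative ({value:.4g}) at t={t:.4g}; integration unstable"
    )


def integrate_ode(
    model: str,
    params: ModelParams,
    T0: float,
    schedule: DoseSchedule,
    t_end: float,
    dt: float = 0.01,
    R0: float = 0.0,
) -> Trajectory:
    """Integrate the base or resistance model with impulsive dosing (RK4).

    Parameters
    ----------
    model
        ``"base"`` (T, C) or ``"resistance"`` (T, C, R).
    T0
        Tumor burden at treatment start, cells.
    schedule
        Impulsive doses; an entry at time 0 sets C(0), otherwise C(0) = 0.
    t_end, dt
        Horizon and fixed step, days.  All dose times must be integer
        multiples of ``dt`` and ``t_end`` must be on-grid and cover the
        last dose.
    """
    if model not in ("base", "resistance"):
        raise ValueError(f"unknown model {model!r}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < schedule.last_time():
        raise ValueError("t_end must cover the last scheduled dose")
    n = _grid_index(t_end, dt, "t_end")
    doses = _dose_steps(schedule, dt, n)

    with_R = model == "resistance"
    T_arr = np.empty(n + 1)
    C_arr = np.empty(n + 1)
    R_arr = np.empty(n + 1) if with_R else None

    c_scale = max(1.0, schedule.total)
    T, C = float(T0), doses.get(0, 0.0)
    R = float(R0)
    T_arr[0], C_arr[0] = T, C
    if with_R:
        R_arr[0] = R

    # local-float kernels of rhs_base / rhs_resistance (hot loop)
    p = params
    rho_T, K, alpha_T = p.rho_T, p.K, p.alpha_T
    rho_C, g_T, alpha_C, g_C = p.rho_C, p.g_T, p.alpha_C, p.g_C
    inv_tau_C, alpha_R = 1.0 / p.tau_C, p.alpha_R
    half, sixth = 0.5 * dt, dt / 6.0

    if with_R:
        def f3(T, C, R):
            s = 1.0 - R
            return (
                rho_T * T * (1.0 - T / K) - alpha_T * s * C * T,
                (rho_C * s * T / (g_T + T) - alpha_C * T / (g_C + C) - inv_tau_C) * C,
                alpha_R * C * s,
            )

        for k in range(n):
            t = k * dt
            a1, b1, c1 = f3(T, C, R)
            a2, b2, c2 = f3(T + half * a1, C + half * b1, min(R + half * c1, 1.0))
            a3, b3, c3 = f3(T + half * a2, C + half * b2, min(R + half * c2, 1.0))
            a4, b4, c4 = f3(T + dt * a3, C + dt * b3, min(R + dt * c3, 1.0))
            T += sixth * (a1 + 2 * a2 + 2 * a3 + a4)
            C += sixth * (b1 + 2 * b2 + 2 * b3 + b4)
            R = min(_guard(R + sixth * (c1 + 2 * c2 + 2 * c3 + c4), 1.0, "R", t), 1.0)
            T = _guard(T, K, "T", t)
            C = _guard(C, c_scale, "C", t)
            m = doses.get(k + 1)
            if m is not None:
                C += m
            T_arr[k + 1], C_arr[k + 1], R_arr[k + 1] = T, C, R
    else:
        def f2(T, C):
            return (
                rho_T * T * (1.0 - T / K) - alpha_T * C * T,
                (rho_C * T / (g_T + T) - alpha_C * T / (g_C + C) - inv_tau_C) * C,
            )

        for k in range(n):
            t = k * dt
            a1, b1 = f2(T, C)
            a2, b2 = f2(T + half * a1, C + half * b1)
            a3, b3 = f2(T + half * a2, C + half * b2)
            a4, b4 = f2(T + dt * a3, C + dt * b3)
            T += sixth * (a1 + 2 * a2 + 2 * a3 + a4)
            C += sixth * (b1 + 2 * b2 + 2 * b3 + b4)
            T = _guard(T, K, "T", t)
            C = _guard(C, c_scale, "C", t)
            m = doses.get(k + 1)
            if m is not None:
                C += m
            T_arr[k + 1], C_arr[k + 1] = T, C

    return Trajectory(
        times=np.arange(n + 1) * dt,
        T=T_arr,
        C=C_arr,
        R=R_arr,
        jump_times=tuple(t for t, _ in schedule.entries),
        meta={
            "model": model,
            "solver": "rk4",
            "dt": dt,
            "T0": T0,
            "schedule": list(schedule.entries),
            "params": {k: getattr(params, k) for k in vars(params)},
        },
    )


def integrate_dde(
    params: ModelParams,
    T0: float,
    schedule: DoseSchedule,
    t_end: float,
    dt: float = 0.01,
) -> Trajectory:
    """Integrate the delayed-activation model (RK2/Heun, method of steps).

    The pre-treatment history is the logistic tumor curve with T(0) = T0 and
    C identically 0 on [-tau, 0); the dose scheduled at t = 0 (if any) is
    the point value C(0), seen by the delayed term when t - tau = 0
    (right-continuous convention).  The lag must be an integer number of
    steps so every lagged lookup falls exactly on the grid and never
    bridges a dose discontinuity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < schedule.last_time():
        raise ValueError("t_end must cover the last scheduled dose")
    if not 0 < T0 < params.K:
        raise ValueError("T0 must satisfy 0 < T0 < K")
    n = _grid_index(t_end, dt, "t_end")
    lag = _grid_index(params.tau, dt, "delay tau") if params.tau > 0 else 0
    doses = _dose_steps(schedule, dt, n)

    T_arr = np.empty(n + 1)
    C_arr = np.empty(n + 1)
    T_arr[0] = T0
    C_arr[0] = doses.get(0, 0.0)
    c_scale = max(1.0, schedule.total)

    # local-float kernel of rhs_delay (hot loop)
    p = params
    rho_T, K, alpha_T = p.rho_T, p.K, p.alpha_T
    rho_C, g_T, alpha_C, g_C = p.rho_C, p.g_T, p.alpha_C, p.g_C
    inv_tau_C = 1.0 / p.tau_C
    half = 0.5 * dt

    def lagged(j: int) -> tuple[float, float]:
        """Right-limit lagged state (post-impulse at jump nodes)."""
        if j >= 0:
            return T_arr[j], C_arr[j]
        return K / (1.0 - (1.0 - K / T0) * math.exp(-rho_T * j * dt)), 0.0

    def lagged_left(j: int) -> tuple[float, float]:
        """Left-limit lagged state: the branch valid on the open interval
        ending at this node (pre-impulse value; C(0^-) = 0)."""
        if j > 0:
            m = doses.get(j)
            return T_arr[j], C_arr[j] if m is None else C_arr[j] - m
        if j == 0:
            return T_arr[0], 0.0
        return K / (1.0 - (1.0 - K / T0) * math.exp(-rho_T * j * dt)), 0.0

    def f(T, C, Tl, Cl):
        return (
            rho_T * T * (1.0 - T / K) - alpha_T * C * T,
            rho_C * Tl * Cl / (g_T + Tl)
            - (alpha_C * T / (g_C + C) + inv_tau_C) * C,
        )

    T, C = float(T_arr[0]), float(C_arr[0])
    for k in range(n):
        t = k * dt
        if lag > 0:
            # predictor sees the right limit at t_k - tau; the corrector,
            # evaluating at the right endpoint of the step, must see the
            # branch valid on the open interval, i.e. the left limit at
            # t_{k+1} - tau (keeps Heun 2nd order across discontinuities)
            Tl, Cl = lagged(k - lag)
            Tl2, Cl2 = lagged_left(k + 1 - lag)
        else:
            # tau = 0 reduces to the base model (Heun)
            Tl, Cl = T, C
        a1, b1 = f(T, C, Tl, Cl)
        Tp, Cp = T + dt * a1, C + dt * b1
        if lag == 0:
            Tl2, Cl2 = Tp, Cp
        a2, b2 = f(Tp, Cp, Tl2, Cl2)
        T += half * (a1 + a2)
        C += half * (b1 + b2)
        T = _guard(T, K, "T", t)
        C = _guard(C, c_scale, "C", t)
        m = doses.get(k + 1)
        if m is not None:
            C += m
        T_arr[k + 1], C_arr[k + 1] = T, C

    return Trajectory(
        times=np.arange(n + 1) * dt,
        T=T_arr,
        C=C_arr,
        R=None,
        jump_times=tuple(t for t, _ in schedule.entries),
        meta={
            "model": "delay",
            "solver": "rk2-heun-steps",
            "dt": dt,
            "T0": T0,
            "schedule": list(schedule.entries),
            "params": {k: getattr(params, k) for k in vars(params)},
        },
    )
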