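"""Morris elementary-effects screening of the model inputs.

One-at-a-time trajectory sampling (Morris design with ``p`` levels and step
``delta = p / (2(p-1))`` on the unit cube) over a +/-20% box around the
reference values of the 11 screened inputs: the model parameters plus the
initial tumor and CAR-T burdens.  For the resistance model the 11th input is
the resistance induction strength ``alpha_R``; for the delay model it is the
activation delay ``tau``.

For each sampled input point the appropriate model is integrated under a
single-dose regime (C0 administered at t = 0, no further doses) and a fixed
set of output functionals is evaluated: tumor and CAR-T burden at days 180,
360 and 540, their time averages over [0, 540], the time for the tumor to
exceed 3.5e10 cells, and the time for the CAR-T population to drop below
1000 cells.  Per input, the mean absolute elementary effect mu* measures
overall influence and the standard deviation sigma flags nonlinearity or
interactions.

All design points for one screen are integrated simultaneously (the state
arrays carry one column per point), which keeps a full screen at r = 50
trajectories to a few seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    C0_SENSITIVITY_DELAY,
    C0_SENSITIVITY_RESISTANCE,
    REFERENCE_PARAMS,
    T0_REFERENCE,
)
from .outcomes import CART_DETECTABILITY_THRESHOLD, TUMOR_CRITICAL_THRESHOLD

__all__ = [
    "InputSpace",
    "MorrisDesign",
    "MorrisResult",
    "resistance_space",
    "delay_space",
    "morris_sample",
    "elementary_effects",
    "morris_stats",
    "normalize_result",
    "output_functionals",
    "evaluate_design",
    "morris_screen",
    "OUTPUT_NAMES",
]

logger = logging.getLogger(__name__)

#: output functionals computed per design point
OUTPUT_NAMES = (
    "T_180", "T_360", "T_540",
    "C_180", "C_360", "C_540",
    "T_avg", "C_avg",
    "time_T_above_3.5e10",
    "time_C_below_1000",
)

_EVAL_DAYS = (180.0, 360.0, 540.0)
_AVG_HORIZON = 540.0
_THRESHOLD_HORIZON = 2500.0  # censoring horizon for the crossing outputs


@dataclass(frozen=True)
class InputSpace:
    """Named box of screened inputs (model parameters + initial conditions)."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names, lower and upper must have equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    def __len__(self) -> int:
        return len(self.names)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Affine map from the unit cube into the box."""
        return self.lower + u * (self.upper - self.lower)

    @property
    def reference(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)


_COMMON = ("rho_T", "K", "alpha_T", "rho_C", "g_T", "alpha_C", "g_C", "tau_C")


def _space(extra: str, c0: float, rel: float) -> InputSpace:
    names = _COMMON + (extra, "T0", "C0")
    ref = np.array(
        [getattr(REFERENCE_PARAMS, n) for n in _COMMON]
        + [getattr(REFERENCE_PARAMS, extra), T0_REFERENCE, c0]
    )
    return InputSpace(names=names, lower=(1 - rel) * ref, upper=(1 + rel) * ref)


def resistance_space(rel: float = 0.2) -> InputSpace:
    """+/-20% box for the resistance model (11 inputs, incl. alpha_R)."""
    return _space("alpha_R", C0_SENSITIVITY_RESISTANCE, rel)


def delay_space(rel: float = 0.2) -> InputSpace:
    """+/-20% box for the delay model (11 inputs, incl. tau)."""
    return _space("tau", C0_SENSITIVITY_DELAY, rel)


@dataclass(frozen=True)
class MorrisDesign:
    """Sampled one-at-a-time design: r trajectories of k+1 points each."""

    space: InputSpace
    unit_points: np.ndarray          # (r*(k+1), k) on the unit cube
    order: np.ndarray                # (r, k) coordinate visited at each step
    signed_step: np.ndarray          # (r, k) signed unit-cube step (+/-delta)
    delta: float

    @property
    def points(self) -> np.ndarray:
        """Design points in actual input units."""
        return self.space.from_unit(self.unit_points)

    @property
    def r(self) -> int:
        return self.order.shape[0]

    @property
    def k(self) -> int:
        return self.order.shape[1]


def morris_sample(
    space: InputSpace,
    r: int,
    p: int = 4,
    seed: Optional[int] = None,
) -> MorrisDesign:
    """Sample a Morris trajectory design.

    Each of the ``r`` trajectories starts at a random point of the p-level
    grid and changes exactly one input per step by ``delta = p/(2(p-1))`` of
    the unit range, visiting every input once in a random order; all points
    stay inside the box.  A fixed ``seed`` makes the design reproducible.
    """
    if p < 2 or p % 2 != 0:
        raise ValueError("number of levels p must be even and >= 2")
    if r < 1:
        raise ValueError("r must be >= 1")
    k = len(space)
    delta = p / (2.0 * (p - 1.0))
    rng = np.random.default_rng(seed)
    levels = np.arange(p) / (p - 1.0)

    pts = np.empty((r * (k + 1), k))
    order = np.empty((r, k), dtype=int)
    steps = np.empty((r, k))
    for j in range(r):
        sign = rng.choice([-1.0, 1.0], size=k)
        # base levels compatible with the step staying inside [0, 1]
        base_idx = rng.integers(0, p // 2, size=k)
        base = np.where(sign > 0, levels[base_idx], levels[base_idx + p // 2])
        perm = rng.permutation(k)
        x = base.copy()
        block = j * (k + 1)
        pts[block] = x
        for s, coord in enumerate(perm):
            x = x.copy()
            x[coord] += sign[coord] * delta
            pts[block + s + 1] = x
        order[j] = perm
        steps[j] = sign[perm] * delta
    if np.any(pts < -1e-12) or np.any(pts > 1 + 1e-12):
        raise AssertionError("design point escaped the unit cube")
    return MorrisDesign(
        space=space,
        unit_points=np.clip(pts, 0.0, 1.0),
        order=order,
        signed_step=steps,
        delta=delta,
    )


def elementary_effects(design: MorrisDesign, outputs: np.ndarray) -> np.ndarray:
    """Per-input elementary-effect samples, shape (k, r).

    ``outputs`` holds the model output at every design point in order.  The
    effect of a step is the output difference divided by the signed
    unit-cube step, so for a linear output f = sum a_i x_i the effect on
    input i is exactly a_i.
    """
    outputs = np.asarray(outputs, dtype=float)
    r, k = design.r, design.k
    if outputs.shape != (r * (k + 1),):
        raise ValueError(f"expected {r * (k + 1)} outputs, got {outputs.shape}")
    ee = np.empty((k, r))
    for j in range(r):
        block = j * (k + 1)
        dy = np.diff(outputs[block : block + k + 1])
        ee[design.order[j], j] = dy / design.signed_step[j]
    return ee


@dataclass(frozen=True)
class MorrisResult:
    """mu* (mean |elementary effect|) and sigma per input, with optional
    max-normalized variants."""

    names: tuple[str, ...]
    mu_star: np.ndarray
    sigma: np.ndarray
    mu_star_norm: Optional[np.ndarray] = None
    sigma_norm: Optional[np.ndarray] = None
    output: str = ""

    def ranking(self) -> tuple[str, ...]:
        """Input names ordered by decreasing mu*."""
        return tuple(
            str(n) for n in np.array(self.names)[np.argsort(-self.mu_star, kind="stable")]
        )

    def to_frame(self) -> pd.DataFrame:
        mu_max = float(np.max(self.mu_star))
        s_max = float(np.max(self.sigma))
        return pd.DataFrame(
            {
                "input": self.names,
                "mu_star": self.mu_star,
                "sigma": self.sigma,
                "mu_star_norm": self.mu_star / mu_max if mu_max > 0 else self.mu_star,
                "sigma_norm": self.sigma / s_max if s_max > 0 else self.sigma,
                "output": self.output,
            }
        )


def morris_stats(
    effects: np.ndarray, names: Sequence[str], output: str = ""
) -> MorrisResult:
    """Reduce elementary-effect samples (k, r) to mu* and sigma per input."""
    effects = np.asarray(effects, dtype=float)
    if effects.ndim != 2:
        raise ValueError("effects must be a (k, r) array")
    if effects.shape[0] != len(names):
        raise ValueError("effects and names lengths differ")
    mu_star = np.mean(np.abs(effects), axis=1)
    sigma = (
        np.std(effects, axis=1, ddof=1)
        if effects.shape[1] > 1
        else np.zeros(effects.shape[0])
    )
    return MorrisResult(names=tuple(names), mu_star=mu_star, sigma=sigma, output=output)


def normalize_result(res: MorrisResult) -> MorrisResult:
    """Scale mu* and sigma by their maxima across inputs (idempotent)."""
    m = float(np.max(res.mu_star))
    if m <= 0:
        raise ValueError("cannot normalize an all-zero mu* vector")
    s = float(np.max(res.sigma))
    return replace(
        res,
        mu_star=res.mu_star / m,
        sigma=res.sigma / s if s > 0 else res.sigma,
        mu_star_norm=res.mu_star / m,
        sigma_norm=res.sigma / s if s > 0 else res.sigma.copy(),
    )


# ---------------------------------------------------------------------------
# batch single-dose simulation of the output functionals

def _unpack(names: tuple[str, ...], pts: np.ndarray) -> dict[str, np.ndarray]:
    return {n: pts[:, i].copy() for i, n in enumerate(names)}


def _finalize_outputs(rec, t_up, t_dn, sumT, sumC, n_avg):
    out = dict(rec)
    for key, arr in (("time_T_above_3.5e10", t_up), ("time_C_below_1000", t_dn)):
        n_cens = int(np.isnan(arr).sum())
        if n_cens:
            logger.warning(
                "%d/%d runs censored for %s; assigning horizon %g",
                n_cens, arr.size, key, _THRESHOLD_HORIZON,
            )
        out[key] = np.where(np.isnan(arr), _THRESHOLD_HORIZON, arr)
    out["T_avg"] = sumT / n_avg
    out["C_avg"] = sumC / n_avg
    return out


def _batch_resistance(v: dict[str, np.ndarray], dt: float) -> dict[str, np.ndarray]:
    m = v["T0"].size
    T, C, R = v["T0"].copy(), v["C0"].copy(), np.zeros(m)
    rec: dict[str, np.ndarray] = {}
    t_up = np.full(m, np.nan)
    t_dn = np.full(m, np.nan)
    sumT = np.zeros(m)
    sumC = np.zeros(m)
    n_avg = 0

    inv_tau = 1.0 / v["tau_C"]

    def f(T, C, R):
        s = 1.0 - R
        dT = v["rho_T"] * T * (1.0 - T / v["K"]) - v["alpha_T"] * s * C * T
        dC = (v["rho_C"] * s * T / (v["g_T"] + T)
              - v["alpha_C"] * T / (v["g_C"] + C) - inv_tau) * C
        dR = v["alpha_R"] * C * s
        return dT, dC, dR

    n_total = int(round(_THRESHOLD_HORIZON / dt))
    n_540 = int(round(_AVG_HORIZON / dt))
    day_steps = {int(round(d / dt)): d for d in _EVAL_DAYS}
    half = 0.5 * dt
    for k in range(n_total):
        if n_avg <= n_540:
            sumT += T
            sumC += C
            n_avg += 1
        a1, b1, c1 = f(T, C, R)
        a2, b2, c2 = f(T + half * a1, C + half * b1, np.minimum(R + half * c1, 1.0))
        a3, b3, c3 = f(T + half * a2, C + half * b2, np.minimum(R + half * c2, 1.0))
        a4, b4, c4 = f(T + dt * a3, C + dt * b3, np.minimum(R + dt * c3, 1.0))
        Tn = np.maximum(T + dt / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4), 0.0)
        Cn = np.maximum(C + dt / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4), 0.0)
        R = np.clip(R + dt / 6.0 * (c1 + 2 * c2 + 2 * c3 + c4), 0.0, 1.0)
        t0, t1 = k * dt, (k + 1) * dt
        _record_crossings(t_up, t_dn, T, C, Tn, Cn, t0, t1)
        T, C = Tn, Cn
        if k + 1 in day_steps:
            d = day_steps[k + 1]
            rec[f"T_{int(d)}"] = T.copy()
            rec[f"C_{int(d)}"] = C.copy()
        if k + 1 >= n_540 and not (np.isnan(t_up).any() or np.isnan(t_dn).any()):
            break
    return _finalize_outputs(rec, t_up, t_dn, sumT, sumC, n_avg)


def _record_crossings(t_up, t_dn, T, C, Tn, Cn, t0, t1):
    hit = np.isnan(t_up) & (T < TUMOR_CRITICAL_THRESHOLD) & (Tn >= TUMOR_CRITICAL_THRESHOLD)
    if hit.any():
        frac = (TUMOR_CRITICAL_THRESHOLD - T[hit]) / (Tn[hit] - T[hit])
        t_up[hit] = t0 + frac * (t1 - t0)
    hit = np.isnan(t_dn) & (C >= CART_DETECTABILITY_THRESHOLD) & (Cn < CART_DETECTABILITY_THRESHOLD)
    if hit.any():
        frac = (C[hit] - CART_DETECTABILITY_THRESHOLD) / (C[hit] - Cn[hit])
        t_dn[hit] = t0 + frac * (t1 - t0)


def _batch_delay(v: dict[str, np.ndarray], dt: float) -> dict[str, np.ndarray]:
    m = v["T0"].size
    # snap each point's lag to the nearest whole number of steps
    lag = np.maximum(np.rint(v["tau"] / dt).astype(int), 1)
    lag_max = int(lag.max())
    bufsize = lag_max + 2
    Tbuf = np.zeros((bufsize, m))
    Cbuf = np.zeros((bufsize, m))
    T, C = v["T0"].copy(), v["C0"].copy()
    Tbuf[0], Cbuf[0] = T, C
    cols = np.arange(m)

    rec: dict[str, np.ndarray] = {}
    t_up = np.full(m, np.nan)
    t_dn = np.full(m, np.nan)
    sumT = np.zeros(m)
    sumC = np.zeros(m)
    n_avg = 0

    inv_tau = 1.0 / v["tau_C"]

    def lagged(j: np.ndarray, left: bool = False) -> tuple[np.ndarray, np.ndarray]:
        # left=True: branch valid on the open interval ending at the node
        # (C(0^-) = 0 rather than the administered dose C0)
        pre = (j < 0) | (left & (j == 0))
        Tl = Tbuf[j % bufsize, cols]
        Cl = Cbuf[j % bufsize, cols]
        if pre.any():
            t_neg = j[pre] * dt
            T0n, Kn, rn = v["T0"][pre], v["K"][pre], v["rho_T"][pre]
            Tl[pre] = Kn / (1.0 - (1.0 - Kn / T0n) * np.exp(-rn * t_neg))
            Cl[pre] = 0.0
        return Tl, Cl

    def f(T, C, Tl, Cl):
        dT = v["rho_T"] * T * (1.0 - T / v["K"]) - v["alpha_T"] * C * T
        dC = (v["rho_C"] * Tl * Cl / (v["g_T"] + Tl)
              - (v["alpha_C"] * T / (v["g_C"] + C) + inv_tau) * C)
        return dT, dC

    n_total = int(round(_THRESHOLD_HORIZON / dt))
    n_540 = int(round(_AVG_HORIZON / dt))
    day_steps = {int(round(d / dt)): d for d in _EVAL_DAYS}
    for k in range(n_total):
        if n_avg <= n_540:
            sumT += T
            sumC += C
            n_avg += 1
        Tl, Cl = lagged(k - lag)
        a1, b1 = f(T, C, Tl, Cl)
        Tl2, Cl2 = lagged(k + 1 - lag, left=True)
        a2, b2 = f(T + dt * a1, C + dt * b1, Tl2, Cl2)
        Tn = np.maximum(T + 0.5 * dt * (a1 + a2), 0.0)
        Cn = np.maximum(C + 0.5 * dt * (b1 + b2), 0.0)
        _record_crossings(t_up, t_dn, T, C, Tn, Cn, k * dt, (k + 1) * dt)
        T, C = Tn, Cn
        idx = (k + 1) % bufsize
        Tbuf[idx], Cbuf[idx] = T, C
        if k + 1 in day_steps:
            d = day_steps[k + 1]
            rec[f"T_{int(d)}"] = T.copy()
            rec[f"C_{int(d)}"] = C.copy()
        if k + 1 >= n_540 and not (np.isnan(t_up).any() or np.isnan(t_dn).any()):
            break
    return _finalize_outputs(rec, t_up, t_dn, sumT, sumC, n_avg)


def evaluate_design(
    model: str, design: MorrisDesign, dt: float = 0.01
) -> dict[str, np.ndarray]:
    """Run the single-dose simulation at every design point.

    Returns one output array (length r*(k+1)) per functional in
    :data:`OUTPUT_NAMES`.  Threshold times that do not occur within the
    2500-day horizon are assigned the horizon value (and logged).
    """
    pts = design.points
    v = _unpack(design.space.names, pts)
    if model == "resistance":
        if "alpha_R" not in v:
            raise ValueError("design does not screen alpha_R (wrong input space?)")
        return _batch_resistance(v, dt)
    if model == "delay":
        if "tau" not in v:
            raise ValueError("design does not screen tau (wrong input space?)")
        return _batch_delay(v, dt)
    raise ValueError(f"unknown model {model!r}")


def output_functionals(
    model: str, point: dict[str, float], dt: float = 0.01
) -> dict[str, float]:
    """Evaluate all output functionals at a single input point.

    ``point`` maps input names (see :func:`resistance_space` /
    :func:`delay_space`) to values.
    """
    names = (resistance_space() if model == "resistance" else delay_space()).names
    missing = set(names) - set(point)
    if missing:
        raise ValueError(f"missing inputs: {sorted(missing)}")
    v = {n: np.array([float(point[n])]) for n in names}
    batch = _batch_resistance(v, dt) if model == "resistance" else _batch_delay(v, dt)
    return {k: float(val[0]) for k, val in batch.items()}


def morris_screen(
    model: str,
    r: int = 50,
    p: int = 4,
    seed: Optional[int] = 0,
    dt: float = 0.01,
    rel: float = 0.2,
) -> dict[str, MorrisResult]:
    """Full Morris screen of one model: sample, simulate, reduce.

    Returns a :class:`MorrisResult` per output functional (raw mu*/sigma;
    apply :func:`normalize_result` for the max-scaled variants).
    """
    space = resistance_space(rel) if model == "resistance" else delay_space(rel)
    design = morris_sample(space, r=r, p=p, seed=seed)
    outputs = evaluate_design(model, design, dt=dt)
    results: dict[str, MorrisResult] = {}
    for name, y in outputs.items():
        ee = elementary_effects(design, y)
        results[name] = morris_stats(ee, space.names, output=name)
    return results
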