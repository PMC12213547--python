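"""Right-hand sides of the tumor--CAR-T interaction models.

Three closely related models of glioblastoma under CAR-T cell therapy are
implemented, all built on logistic tumor growth with a saturating CAR-T
response:

* **base** -- two ODEs for tumor cells ``T`` and CAR-T cells ``C``.  The tumor
  grows logistically toward the carrying capacity ``K`` and is killed by
  CAR-T cells through a bilinear term.  CAR-T cells proliferate on contact
  with tumor cells (Michaelis-Menten in ``T``), are inactivated by the tumor
  (saturating in ``C``), and die naturally with mean lifetime ``tau_C``.
* **resistance** -- adds a dimensionless resistance strength ``R`` in [0, 1)
  that accrues in proportion to the CAR-T burden and scales down both the
  kill rate and the CAR-T proliferation rate by ``(1 - R)``.  Used for
  intracranial, antigen-loss-prone protocols (IL13Ralpha2).
* **delay** -- replaces the proliferation term by its value at ``t - tau``,
  modelling the time intravenously infused CAR-T cells need to cross the
  blood-brain barrier and activate at the tumor site (HER2, EGFRvIII).

All populations are absolute cell counts and time is measured in days.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "ModelParams",
    "SystemState",
    "REFERENCE_PARAMS",
    "T0_REFERENCE",
    "C0_SENSITIVITY_RESISTANCE",
    "C0_SENSITIVITY_DELAY",
    "rhs_base",
    "rhs_resistance",
    "rhs_delay",
    "logistic_history",
    "params_to_config",
    "params_from_config",
]

ArrayLike = Union[float, np.ndarray]


def _require_finite(name: str, value: ArrayLike) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"non-finite value in {name!r}")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants, capacities and saturation levels of the models.

    Defaults are the reference parameter set used throughout: tumor growth
    calibrated to glioblastoma (net growth 0.01/day toward a carrying
    capacity of 2e12 cells), CAR-T kinetics from published CAR-T/glioma
    modelling work, an activation delay of 2 days, and a resistance
    induction strength of 8e-10 per CAR-T cell per day.

    Units: rates in day^-1, populations in cells, ``alpha_T`` and
    ``alpha_R`` in cell^-1 day^-1, ``tau_C`` and ``tau`` in days.
    ``alpha_R`` matters only for the resistance model, ``tau`` only for
    the delay model.
    """

    rho_T: float = 0.01       # tumor net growth rate, day^-1
    K: float = 2e12           # tumor carrying capacity, cells
    alpha_T: float = 2.5e-10  # tumor kill rate by CAR-T, cell^-1 day^-1
    rho_C: float = 0.9        # max CAR-T proliferation rate, day^-1
    g_T: float = 1e10         # tumor half-saturation level, cells
    alpha_C: float = 0.05     # max CAR-T inactivation rate, day^-1
    g_C: float = 2e9          # CAR-T half-saturation level, cells
    tau_C: float = 7.0        # mean CAR-T lifetime at the tumor site, days
    alpha_R: float = 8e-10    # resistance induction strength, cell^-1 day^-1
    tau: float = 2.0          # CAR-T activation delay, days

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v}")
            if f.name in ("tau", "alpha_R"):
                # zero switches the delay / resistance extension off,
                # recovering the base model exactly
                if v < 0:
                    raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")

    def with_overrides(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given parameters replaced."""
        return replace(self, **kwargs)


#: Reference parameter set (single source of truth for all presets).
REFERENCE_PARAMS = ModelParams()

#: Reference initial tumor burden, cells (~1 cm radius glioblastoma scale).
T0_REFERENCE = 1.5e10

#: Initial CAR-T dose used for sensitivity screening of the resistance model.
C0_SENSITIVITY_RESISTANCE = 2e7

#: Initial CAR-T dose used for sensitivity screening of the delay model.
C0_SENSITIVITY_DELAY = 5e8


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: tumor cells, CAR-T cells and (optionally) the
    resistance strength ``R`` in [0, 1]."""

    T: float
    C: float
    R: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite("T", self.T)
        _require_finite("C", self.C)
        if self.T < 0 or self.C < 0:
            raise ValueError("populations must be nonnegative")
        if self.R is not None:
            _require_finite("R", self.R)
            if not 0.0 <= self.R <= 1.0:
                raise ValueError(f"R must lie in [0, 1], got {self.R}")


def rhs_base(T: ArrayLike, C: ArrayLike, params: ModelParams):
    """Time derivatives (dT/dt, dC/dt) of the base model, cells/day.

    dT/dt = rho_T T (1 - T/K) - alpha_T C T
    dC/dt = (rho_C T/(g_T+T) - alpha_C T/(g_C+C) - 1/tau_C) C
    """
    _require_finite("T", T)
    _require_finite("C", C)
    p = params
    dT = p.rho_T * T * (1.0 - T / p.K) - p.alpha_T * C * T
    dC = (p.rho_C * T / (p.g_T + T) - p.alpha_C * T / (p.g_C + C) - 1.0 / p.tau_C) * C
    return dT, dC


def rhs_resistance(T: ArrayLike, C: ArrayLike, R: ArrayLike, params: ModelParams):
    """Derivatives (dT/dt, dC/dt, dR/dt) of the resistance-augmented model.

    The kill and proliferation terms of the base model are scaled by
    ``(1 - R)``; resistance accrues as dR/dt = alpha_R C (1 - R), so R is
    nondecreasing for C >= 0 and can never cross 1.
    """
    _require_finite("T", T)
    _require_finite("C", C)
    _require_finite("R", R)
    if np.any(np.asarray(R) < 0) or np.any(np.asarray(R) > 1):
        raise ValueError("R must lie in [0, 1]")
    p = params
    s = 1.0 - R
    dT = p.rho_T * T * (1.0 - T / p.K) - p.alpha_T * s * C * T
    dC = (p.rho_C * s * T / (p.g_T + T) - p.alpha_C * T / (p.g_C + C) - 1.0 / p.tau_C) * C
    dR = p.alpha_R * C * s
    return dT, dC, dR


def rhs_delay(
    T: ArrayLike,
    C: ArrayLike,
    T_lag: ArrayLike,
    C_lag: ArrayLike,
    params: ModelParams,
):
    """Derivatives (dT/dt, dC/dt) of the delayed-activation model.

    The CAR-T proliferation term is evaluated at the lagged state
    ``(T_lag, C_lag) = (T(t - tau), C(t - tau))``; with ``lagged == current``
    this reduces exactly to :func:`rhs_base`.
    """
    _require_finite("T", T)
    _require_finite("C", C)
    _require_finite("T_lag", T_lag)
    _require_finite("C_lag", C_lag)
    p = params
    dT = p.rho_T * T * (1.0 - T / p.K) - p.alpha_T * C * T
    dC = (
        p.rho_C * T_lag * C_lag / (p.g_T + T_lag)
        - (p.alpha_C * T / (p.g_C + C) + 1.0 / p.tau_C) * C
    )
    return dT, dC


def logistic_history(t: ArrayLike, T0: ArrayLike, params: ModelParams):
    """Closed-form logistic tumor size at time ``t`` with ``T(0) = T0``.

    T(t) = K / (1 - (1 - K/T0) exp(-rho_T t))

    Serves as the pre-treatment history of the delay model on [-tau, 0] and,
    for t > 0, as the untreated-growth analytic solution used by tests.
    """
    _require_finite("t", t)
    T0a = np.asarray(T0, dtype=float)
    if np.any(T0a <= 0) or np.any(T0a >= params.K):
        raise ValueError("T0 must satisfy 0 < T0 < K")
    return params.K / (1.0 - (1.0 - params.K / T0a) * np.exp(-params.rho_T * np.asarray(t, dtype=float)))


# ---------------------------------------------------------------------------
# flat key=value config (plain text, one parameter per line)

def params_to_config(params: ModelParams, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a parameter set as ``key = value`` lines; optionally write it."""
    buf = io.StringIO()
    for f in fields(params):
        buf.write(f"{f.name} = {getattr(params, f.name)!r}\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_config(source: Union[str, Path]) -> ModelParams:
    """Parse a parameter set from config text or a file path.

    Unknown keys are rejected by name; missing keys fall back to the
    reference values.
    """
    p = Path(source) if isinstance(source, Path) else None
    if p is None and isinstance(source, str) and "\n" not in source and "=" not in source:
        p = Path(source)
    text = p.read_text() if p is not None else str(source)
    known = {f.name for f in fields(ModelParams)}
    overrides: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ValueError(f"unknown parameter {key!r}")
        overrides[key] = float(val.strip())
    return ModelParams(**overrides)
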