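"""Named simulation scenarios, plain-text configs, and protocol sweeps.

A :class:`Scenario` bundles everything one simulation needs — model choice,
parameters, dose schedule, horizon, step and endpoints — and presets
reproduce the figure-level scenarios of the three clinical protocols.
Sweeps scan dose size, dose count and inter-dose interval and tabulate an
endpoint per grid cell.

Scenario configs are flat ``key = value`` text files, e.g.::

    name = fig5-egfr
    model = delay
    schedule = egfr:5e8
    horizon = 800
    endpoints = ttp, peak_time:C, first_below:C:1000
    param.tau = 2

Schedule strings: ``il13``, ``egfr[:dose]``, ``her2:dose:n_additional:interval``,
``il13_variant:n_doses:interval`` or explicit ``time:dose`` pairs separated
by commas.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .dynamics import (
    REFERENCE_PARAMS,
    T0_REFERENCE,
    ModelParams,
)
from .integrators import DoseSchedule, Trajectory, integrate_dde, integrate_ode
from .outcomes import Endpoint, evaluate_endpoint
from .protocols import (
    build_egfr_schedule,
    build_her2_schedule,
    build_il13_schedule,
    build_il13_variant,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "run_scenario",
    "run_sweep",
    "scenario_from_config",
    "parse_endpoint",
    "parse_schedule",
    "list_presets",
    "load_preset",
]

logger = logging.getLogger(__name__)

_MODELS = ("base", "resistance", "delay")
_PRESET_DIR = Path(__file__).parent / "presets"


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation run."""

    name: str
    model: str
    schedule: DoseSchedule
    horizon: float
    T0: float = T0_REFERENCE
    params: ModelParams = REFERENCE_PARAMS
    dt: float = 0.01
    endpoints: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.horizon < self.schedule.last_time():
            raise ValueError("horizon must cover the last scheduled dose")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for token in self.endpoints:
            parse_endpoint(token)  # validates


@dataclass
class ScenarioResult:
    scenario: Scenario
    trajectory: Trajectory
    endpoints: dict[str, dict]

    def endpoint_records(self) -> list[dict]:
        return [
            {"scenario": self.scenario.name, "endpoint": k, **v}
            for k, v in self.endpoints.items()
        ]


def parse_endpoint(token: str) -> Endpoint:
    """Parse an endpoint token such as ``ttp``, ``value_at:T:540``,
    ``first_below:C:1000``, ``max_value:R`` or ``peak_time:C``."""
    parts = token.strip().split(":")
    kind = parts[0]
    if kind == "ttp":
        baseline = float(parts[1]) if len(parts) > 1 else None
        return Endpoint(kind="TTP", variable="T", threshold=baseline)
    if kind in ("first_above", "first_below"):
        if len(parts) != 3:
            raise ValueError(f"endpoint {token!r}: expected {kind}:VAR:THRESHOLD")
        return Endpoint(kind=kind, variable=parts[1], threshold=float(parts[2]))
    if kind == "value_at":
        if len(parts) != 3:
            raise ValueError(f"endpoint {token!r}: expected value_at:VAR:DAY")
        return Endpoint(kind=kind, variable=parts[1], day=float(parts[2]))
    if kind in ("peak_time", "max_value"):
        if len(parts) != 2:
            raise ValueError(f"endpoint {token!r}: expected {kind}:VAR")
        return Endpoint(kind=kind, variable=parts[1])
    raise ValueError(f"unknown endpoint kind {kind!r}")


def parse_schedule(spec: str) -> DoseSchedule:
    """Build a :class:`DoseSchedule` from a schedule string (see module doc)."""
    spec = spec.strip()
    head, *args = spec.split(":")
    if head == "il13" and not args:
        return build_il13_schedule()
    if head == "egfr":
        return build_egfr_schedule(float(args[0])) if args else build_egfr_schedule()
    if head == "her2":
        if len(args) != 3:
            raise ValueError("her2 schedule needs dose:n_additional:interval")
        return build_her2_schedule(float(args[0]), int(args[1]), float(args[2]))
    if head == "il13_variant":
        if len(args) != 2:
            raise ValueError("il13_variant schedule needs n_doses:interval")
        return build_il13_variant(int(args[0]), float(args[1]))
    # explicit time:dose pairs
    entries = []
    for pair in spec.split(","):
        t, _, m = pair.partition(":")
        if not m:
            raise ValueError(f"cannot parse schedule entry {pair!r}")
        entries.append((float(t), float(m)))
    return DoseSchedule(entries)


def run_scenario(
    s: Scenario, outdir: Optional[Union[str, Path]] = None
) -> ScenarioResult:
    """Integrate a scenario and evaluate its endpoints.

    Deterministic: identical inputs produce identical outputs.  With
    ``outdir`` set, writes ``<name>.csv`` (+ metadata sidecar) and
    ``<name>.endpoints.json``.
    """
    logger.info(
        "run_scenario %s: model=%s doses=%d horizon=%g dt=%g (gliocart %s)",
        s.name, s.model, len(s.schedule), s.horizon, s.dt, _version(),
    )
    if s.model == "delay":
        traj = integrate_dde(s.params, s.T0, s.schedule, s.horizon, s.dt)
    else:
        traj = integrate_ode(s.model, s.params, s.T0, s.schedule, s.horizon, s.dt)
    traj.meta["scenario"] = s.name
    endpoints = {tok: evaluate_endpoint(traj, parse_endpoint(tok)) for tok in s.endpoints}
    result = ScenarioResult(scenario=s, trajectory=traj, endpoints=endpoints)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        traj.to_csv(outdir / f"{s.name}.csv")
        (outdir / f"{s.name}.endpoints.json").write_text(
            json.dumps(result.endpoint_records(), indent=2)
        )
    return result


def _version() -> str:
    try:
        return _pkg_version("gliocart")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# config parsing

_SCALAR_KEYS = {"name", "model", "schedule", "horizon", "T0", "dt", "endpoints", "kind"}


def _parse_kv(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def scenario_from_config(source: Union[str, Path]) -> Scenario:
    """Load a scenario from config text or a file path.

    Invalid keys are rejected with the offending key named.
    """
    p = Path(source)
    text = p.read_text() if (isinstance(source, Path) or p.suffix == ".cfg") else str(source)
    kv = _parse_kv(text)
    from dataclasses import fields as _fields

    known_params = {f.name for f in _fields(ModelParams)}
    overrides: dict[str, float] = {}
    for key in list(kv):
        if key.startswith("param."):
            pname = key[len("param."):]
            if pname not in known_params:
                raise ValueError(f"invalid config key {key!r}: unknown parameter")
            overrides[pname] = float(kv.pop(key))
        elif key not in _SCALAR_KEYS:
            raise ValueError(f"invalid config key {key!r}")
    if kv.get("kind", "scenario") != "scenario":
        raise ValueError(f"config is of kind {kv['kind']!r}, not a scenario")
    missing = {"name", "model", "schedule", "horizon"} - set(kv)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    params = REFERENCE_PARAMS.with_overrides(**overrides) if overrides else REFERENCE_PARAMS
    endpoints = tuple(
        tok.strip() for tok in kv.get("endpoints", "").split(",") if tok.strip()
    )
    return Scenario(
        name=kv["name"],
        model=kv["model"],
        schedule=parse_schedule(kv["schedule"]),
        horizon=float(kv["horizon"]),
        T0=float(kv.get("T0", T0_REFERENCE)),
        params=params,
        dt=float(kv.get("dt", 0.01)),
        endpoints=endpoints,
    )


def list_presets() -> list[str]:
    """Names of the bundled scenario/sweep presets."""
    return sorted(p.stem for p in _PRESET_DIR.glob("*.cfg"))


def load_preset(name: str):
    """Load a bundled preset by name.

    Returns a :class:`Scenario` for simulation presets and a dict of sweep
    settings for ``*-sweep`` presets.
    """
    path = _PRESET_DIR / f"{name}.cfg"
    if not path.exists():
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}")
    kv = _parse_kv(path.read_text())
    if kv.get("kind", "scenario") == "sweep":
        return kv
    return scenario_from_config(path)


# ---------------------------------------------------------------------------
# sweeps

def run_sweep(
    family: str,
    endpoint: str,
    doses: Sequence[float] = (),
    n_additional: Sequence[int] = (),
    intervals: Sequence[float] = (),
    n_doses: Sequence[int] = (),
    horizon: float = 540.0,
    dt: float = 0.01,
    params: ModelParams = REFERENCE_PARAMS,
    T0: float = T0_REFERENCE,
) -> pd.DataFrame:
    """Tabulate one endpoint over a protocol grid.

    ``family="her2"`` (delay model) scans ``doses x n_additional x
    intervals``; ``family="il13"`` (resistance model) scans ``n_doses x
    intervals`` with the dose fixed by the equal-split rule.  Every grid
    cell contributes exactly one row; censored endpoints are flagged, not
    dropped.
    """
    rows = []
    if family == "her2":
        axes = itertools.product(doses, n_additional, intervals)
        for dose, n_add, interval in axes:
            sched = build_her2_schedule(dose, n_add, interval)
            s = Scenario(
                name=f"her2-{dose:g}-{n_add}x{interval:g}",
                model="delay",
                schedule=sched,
                horizon=horizon,
                T0=T0,
                params=params,
                dt=dt,
                endpoints=(endpoint,),
            )
            res = run_scenario(s).endpoints[endpoint]
            rows.append(
                {
                    "dose": dose,
                    "n_additional": n_add,
                    "interval": interval,
                    "value": res["value"],
                    "censored": res["censored"],
                }
            )
    elif family == "il13":
        for n, interval in itertools.product(n_doses, intervals):
            sched = build_il13_variant(n, interval)
            s = Scenario(
                name=f"il13-{n}x{interval:g}",
                model="resistance",
                schedule=sched,
                horizon=horizon,
                T0=T0,
                params=params,
                dt=dt,
                endpoints=(endpoint,),
            )
            res = run_scenario(s).endpoints[endpoint]
            rows.append(
                {
                    "n_doses": n,
                    "interval": interval,
                    "value": res["value"],
                    "censored": res["censored"],
                }
            )
    else:
        raise ValueError(f"unknown sweep family {family!r}")
    return pd.DataFrame(rows)


def run_sweep_config(kv: dict[str, str]) -> pd.DataFrame:
    """Run a sweep described by a ``kind = sweep`` preset/config mapping."""
    def _floats(key: str) -> tuple[float, ...]:
        return tuple(float(x) for x in kv.get(key, "").split(",") if x.strip())

    def _ints(key: str) -> tuple[int, ...]:
        return tuple(int(x) for x in kv.get(key, "").split(",") if x.strip())

    allowed = {"kind", "family", "endpoint", "doses", "n_additional",
               "intervals", "n_doses", "horizon", "dt"}
    for key in kv:
        if key not in allowed:
            raise ValueError(f"invalid sweep config key {key!r}")
    return run_sweep(
        family=kv["family"],
        endpoint=kv["endpoint"],
        doses=_floats("doses"),
        n_additional=_ints("n_additional"),
        intervals=_floats("intervals"),
        n_doses=_ints("n_doses"),
        horizon=float(kv.get("horizon", 540.0)),
        dt=float(kv.get("dt", 0.01)),
    )
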