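"""Clinical CAR-T dose schedules and body-surface-area dosing.

Three trial-inspired protocols are provided:

* **IL13Ralpha2** (intracranial, resistance model): an initial dose of 2e6
  cells, then 19 weekly doses of 1e7 cells with a 5-week break between the
  15th and 16th of them.
* **HER2/CMV** (intravenous, delay model): an initial dose followed by up to
  six additional equal doses at a fixed interval of 6-12 weeks; doses are
  prescribed per m^2 of body surface (1e6-1e8 cells/m^2) converted with the
  Haycock formula, giving 1.89e6-1.89e8 cells for a 70 kg / 180 cm patient.
* **EGFRvIII** (intravenous, delay model): a single dose of 5e8 cells at
  treatment start.
"""

from __future__ import annotations

from dataclasses import dataclass

from .integrators import DoseSchedule

__all__ = [
    "PatientSpec",
    "REFERENCE_PATIENT",
    "haycock_bsa",
    "build_il13_schedule",
    "build_il13_variant",
    "build_her2_schedule",
    "build_egfr_schedule",
    "equal_split_dose",
    "IL13_FIRST_DOSE",
    "IL13_TOTAL_SUBSEQUENT",
]

#: fixed initial IL13Ralpha2 dose, cells
IL13_FIRST_DOSE = 2e6

#: total cells across the 19 subsequent IL13Ralpha2 doses (19 x 1e7)
IL13_TOTAL_SUBSEQUENT = 1.9e8


@dataclass(frozen=True)
class PatientSpec:
    """Anthropometrics used for per-m^2 dose conversion."""

    weight: float  # kg
    height: float  # cm

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")


REFERENCE_PATIENT = PatientSpec(weight=70.0, height=180.0)


def haycock_bsa(patient: PatientSpec) -> float:
    """Body surface area in m^2 by the Haycock formula.

    BSA = 0.024265 * weight^0.5378 * height^0.3964  (weight kg, height cm).
    For the 70 kg / 180 cm reference patient this gives 1.89 m^2, so the
    1e6-1e8 cells/m^2 prescription spans 1.89e6-1.89e8 cells per dose.
    """
    return 0.024265 * patient.weight**0.5378 * patient.height**0.3964


def build_il13_schedule() -> DoseSchedule:
    """The 20-dose IL13Ralpha2 protocol.

    2e6 cells at day 0; 1e7 cells weekly on days 7..105 (15 doses); a
    5-week break; then 1e7 cells weekly on days 140..161 (4 doses).
    """
    entries = [(0.0, IL13_FIRST_DOSE)]
    entries += [(float(d), 1e7) for d in range(7, 106, 7)]
    entries += [(float(d), 1e7) for d in range(140, 162, 7)]
    return DoseSchedule(entries)


def equal_split_dose(total: float, i: int) -> float:
    """Size of each dose when ``total`` cells are split into ``i`` equal doses.

    d_i = total / i for i = 1..19; the protocol sweep fixes
    total = 1.9e8 cells (the amount delivered by 19 doses of 1e7).
    """
    if not 1 <= i <= 19:
        raise ValueError("number of doses must be between 1 and 19")
    if total <= 0:
        raise ValueError("total must be positive")
    return total / i


def build_il13_variant(n_doses: int, interval: float) -> DoseSchedule:
    """IL13Ralpha2 sweep variant: fixed 2e6 initial dose, then ``n_doses``
    equal doses of 1.9e8/n_doses cells every ``interval`` days.

    Total administered cells are conserved at 1.9e8 + 2e6 for every
    (n_doses, interval) combination.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    d = equal_split_dose(IL13_TOTAL_SUBSEQUENT, n_doses)
    entries = [(0.0, IL13_FIRST_DOSE)]
    entries += [(interval * j, d) for j in range(1, n_doses + 1)]
    return DoseSchedule(entries)


def build_her2_schedule(dose: float, n_additional: int, interval: float) -> DoseSchedule:
    """HER2/CMV protocol: an initial dose plus ``n_additional`` (0-6) equal
    doses every ``interval`` days (a whole number of days)."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if not 0 <= n_additional <= 6:
        raise ValueError("protocol allows at most 6 additional doses (7 cycles)")
    if interval != int(interval) or interval <= 0:
        raise ValueError("interval must be a positive whole number of days")
    return DoseSchedule([(float(interval) * j, dose) for j in range(n_additional + 1)])


def build_egfr_schedule(dose: float = 5e8) -> DoseSchedule:
    """EGFRvIII protocol: one dose at treatment start."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    return DoseSchedule([(0.0, dose)])
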