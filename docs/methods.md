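# Methods

## Models and assumptions

The package implements three nested population models of glioblastoma under
CAR-T cell therapy. All state variables are absolute cell counts (no spatial
structure, no immune compartments beyond CAR-T cells) and time is in days.

**Base model.** Tumor cells `T` follow logistic growth toward a carrying
capacity `K` and are killed through a bilinear tumor–CAR-T interaction.
CAR-T cells `C` proliferate on tumor contact with a saturating
(Michaelis–Menten) dependence on tumor size, are inactivated by the tumor
with a rate saturating in `C`, and die naturally with mean lifetime `τ_C`:

```
dT/dt = ρ_T T (1 − T/K) − α_T C T
dC/dt = ( ρ_C T/(g_T + T) − α_C T/(g_C + C) − 1/τ_C ) C
```

**Resistance model** adds `dR/dt = α_R C (1 − R)` with `R(0) = 0` and scales
`α_T` and `ρ_C` by `(1 − R)`. `R` is nondecreasing whenever `C ≥ 0` and can
never cross 1 (the derivative vanishes there), so resistance saturates. This
variant represents the intracranial IL13Rα2 protocol, where antigen-loss
driven resistance dominated the clinical course.

**Delay model** evaluates the proliferation term at `t − τ`:
`dC/dt = ρ_C T(t−τ) C(t−τ)/(g_T + T(t−τ)) − (α_C T/(g_C + C) + 1/τ_C) C`,
with `τ` the time intravenously infused cells need to reach and activate at
the tumor site. The pre-treatment history is the closed-form logistic curve
through `T(0) = T₀` with `C ≡ 0` on `[−τ, 0)` and a point dose `C(0) = C₀`.
With `τ = 0` (or lagged state equal to the current one) the model reduces
exactly to the base model; with `α_R = 0` so does the resistance model. Both
reductions are enforced by tests.

## Reference parameters

The single source-of-truth default set (`ModelParams()`):

| parameter | meaning | value | units |
|---|---|---|---|
| ρ_T | tumor net growth rate | 0.01 | day⁻¹ |
| K | tumor carrying capacity | 2×10¹² | cells |
| α_T | kill rate by CAR-T | 2.5×10⁻¹⁰ | cell⁻¹ day⁻¹ |
| ρ_C | max CAR-T proliferation | 0.9 | day⁻¹ |
| g_T | tumor half-saturation | 1×10¹⁰ | cells |
| α_C | max CAR-T inactivation | 0.05 | day⁻¹ |
| g_C | CAR-T half-saturation | 2×10⁹ | cells |
| τ_C | mean CAR-T lifetime | 7 | days |
| α_R | resistance induction | 8×10⁻¹⁰ | cell⁻¹ day⁻¹ |
| τ | activation delay | 2 | days |

Initial tumor burden `T₀ = 1.5×10¹⁰` cells (a ≈ 1 cm radius lesion at
glioblastoma cell density; roughly one third of the lethal burden). `α_R`
carries units cell⁻¹ day⁻¹ by dimensional analysis of `dR/dt = α_R C (1−R)`.
With these values the simulated endpoints reproduce the published
protocol-comparison results to a fraction of a percent, which is the
package's calibration check. Parameter sets are serializable to flat
`key = value` config files and overridable per scenario (`param.*` keys).

## Dosing protocols

Impulsive dosing: a `DoseSchedule` is an ordered list of `(day, cells)`; at
each dose time the left limit of `C` is incremented by the dose, `T` and `R`
carry over continuously. Simultaneous entries are additive. Built-ins:

* **IL13Rα2** — 2×10⁶ cells at day 0, then 19 doses of 1×10⁷ weekly (days
  7–105), a 5-week break, days 140–161; 20 doses total. The sweep variant
  splits the same subsequent total (1.9×10⁸ cells, `d_i = 1.9×10⁸ / i`,
  i = 1…19) over `i` doses at a chosen spacing, conserving total cells.
* **HER2/CMV** — an initial dose plus up to six additional equal doses
  (protocol cap of seven cycles) at a whole-day interval, nominally 6–12
  weeks; interval sweeps explore 1–15 weeks. Per-m² prescriptions
  (10⁶–10⁸ cells/m²) convert through the Haycock body-surface-area formula
  `BSA = 0.024265 w^0.5378 h^0.3964` (w kg, h cm). For the 70 kg / 180 cm
  reference patient this gives 1.867 m²; the protocol dose levels
  (1.89×10⁶/10⁷/10⁸ cells) are carried as the published literal values,
  which correspond to a slightly larger BSA estimate (≈ 1.89 m², the Du
  Bois value).
* **EGFRvIII** — a single dose of 5×10⁸ cells at day 0.

The catheter replacement mid-way through the IL13Rα2 course has no
dynamical consequence and is not represented.

## Numerical scheme

Fixed-step integration, classical RK4 for the ODE models and RK2 (Heun) by
the method of steps for the delay model; default `dt = 0.01` day, so whole-
day dose times and the 2-day delay are exactly on-grid. No adaptive
stepping: endpoints are defined on a fixed, documented resolution, and a
grid-refinement test pins the day-540 burden to < 0.1% change under step
halving and the time to progression to < 1 day.

Details that matter for correctness:

* Dose times must be integer multiples of `dt`; off-grid times are rejected
  rather than rounded. Trajectories store the post-impulse (right) value at
  dose times and record jump times.
* In the delay model, lagged lookups fall exactly on the grid (the lag must
  divide `dt` evenly). The Heun *predictor* stage sees the right limit of
  the lagged state; the *corrector*, which evaluates at the right endpoint
  of the step, sees the **left** limit — the branch valid on the open
  interval. Using the post-jump value there would degrade the scheme to
  first order across the history and dose discontinuities (the lagged
  CAR-T term jumps at `t = τ` and at each dose time + τ); with the left
  limit the empirical order is ≥ 1.8, and RK4 measures ≥ 3.5 on smooth
  problems.
* A lagged lookup at exactly `t − τ = 0` uses `C(0) = C₀` (the administered
  dose, right-continuous), consistent with the point-mass initial condition.
* Negative populations within `10⁻⁹` of the relevant scale (K for the
  tumor, the total administered dose for CAR-T) are clamped to zero as
  solver noise; anything larger, or any non-finite value, aborts with a
  diagnostic rather than being masked.

## Endpoints

**Time to progression (TTP)** is the first upward crossing of the baseline
(default: tumor size at treatment start) *after* the tumor has first dropped
below it; a tumor that never regresses has TTP = 0, and one that has not
returned within the horizon is censored. The alternative reading — first
time `T ≥ baseline` — is degenerate (always 0 when `T(0)` equals the
baseline) and inconsistent with the published protocol comparisons.
Crossings are located by linear interpolation on the grid; at `dt = 0.01`
day sub-step root polishing changes nothing at the reported precision.
Default horizons: 2500 days for TTP sweeps, 540 days for burden endpoints.
"Undetectable" CAR-T is operationalized as `C < 1000` cells, the clinical
monitoring threshold; the critical tumor threshold is 3.5×10¹⁰ cells.

## Sensitivity screening

Morris one-at-a-time screening over a ±20% box around the reference values
of 11 inputs (eight shared rate/saturation parameters, `T₀`, `C₀`, plus
`α_R` for the resistance model or `τ` for the delay model), under a
single-dose regime (`C₀` = 2×10⁷ cells for the resistance model, 5×10⁸ for
the delay model; cyclic dosing deliberately excluded). Outputs: `T` and `C`
at days 180/360/540, their time averages over [0, 540], and the two
threshold times; threshold times not reached within 2500 days are assigned
the horizon value and logged.

The screening settings are r = 50 trajectories, p = 4 levels
(Δ = 2/3 of the unit range), fixed seed, all configurable — standard
screening practice sufficient for stable rankings of the dominant inputs.
Elementary effects are exact for linear functions (a test enforces
μ*ᵢ = |aᵢ|, σᵢ = 0). Because Morris perturbs `τ` continuously, the
sensitivity driver snaps each sampled `τ` to the nearest grid multiple of
`dt` (a ≤ 0.5% perturbation at the default step); the user-facing DDE
integrator keeps the strict divisibility precondition. All design points of
a screen are integrated simultaneously as array columns, so a full screen
takes seconds. Only the robust rankings are asserted in tests (the dominant
input per output and the top pair for the tumor-threshold time): ranks
further down the list swap between near-tied inputs across design seeds.

## Design choices on open points

* The reference ρ_T is 0.01 day⁻¹; with it, all seven HER2-family
  progression times and both low-dose day-540 burdens reproduce to < 0.5%,
  which fixes the value empirically against the published results (the
  nearby alternative 0.012 fails by an order of magnitude on the long
  protocols).
* The 7.23×10⁷-cell dose of the interval sweep is treated as a literal
  input, not derived from a per-m² prescription.
* Scenario runs log the package version, parameters, schedule, step and
  solver to a JSON sidecar next to the trajectory CSV; identical inputs
  produce byte-identical outputs.

## Known limitations

* Two immune-axis simplifications are inherited from the models themselves:
  no effector compartments beyond CAR-T cells, and purely logistic growth.
* The simulated single-dose EGFRvIII kinetics disagree with the published
  narrative for that scenario (simulated CAR-T peak near day 19 and
  detectability beyond day 100, versus a reported peak window of days 3–10
  and loss by day 30; simulated TTP ≈ 476 days versus a reported ≈ 425).
  An independent adaptive DDE solver reproduces this package's numbers to
  < 0.1%, so the discrepancy lies between the stated model/parameters and
  that narrative, not in the integration. The corresponding checks are kept
  in the test suite as printed and fail.
* Censoring threshold times at the 2500-day horizon biases Morris effects
  toward zero for inputs whose variation pushes events past the horizon; at
  the reference conditions no run is censored.
* TTP is a deterministic trajectory functional — no inter-patient
  variability or survival statistics.
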