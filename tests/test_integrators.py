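"""Fixed-step integrators: analytic limits, impulse handling, convergence."""

import numpy as np
import pytest

from gliocart import (
    DoseSchedule,
    Trajectory,
    integrate_dde,
    integrate_ode,
    logistic_history,
)

EMPTY = DoseSchedule([])


class TestDoseSchedule:
    def test_orders_and_validates(self):
        with pytest.raises(ValueError):
            DoseSchedule([(7.0, 1e7), (0.0, 2e6)])
        with pytest.raises(ValueError):
            DoseSchedule([(0.0, -1.0)])
        with pytest.raises(ValueError):
            DoseSchedule([(-1.0, 1e7)])

    def test_merges_simultaneous_doses(self):
        s = DoseSchedule([(0.0, 1e7), (0.0, 2e7), (7.0, 5e6)])
        assert s.entries == ((0.0, 3e7), (7.0, 5e6))
        assert s.initial_dose == 3e7

    def test_csv_round_trip(self, tmp_path):
        s = DoseSchedule([(0.0, 2e6), (7.0, 1e7)])
        path = tmp_path / "sched.csv"
        s.to_csv(path)
        assert DoseSchedule.from_csv(path).entries == s.entries


class TestTrajectory:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.arange(3.0), T=np.ones(3), C=np.ones(2))

    def test_csv_and_sidecar(self, tmp_path, params, T0):
        traj = integrate_ode("base", params, T0, EMPTY, 1.0, 0.5)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        data = np.loadtxt(out, delimiter=",", skiprows=1)
        assert data.shape == (3, 3)
        assert (tmp_path / "traj.csv.meta.json").exists()


class TestOdeIntegrator:
    def test_dose_free_matches_closed_form_logistic(self, params, T0):
        traj = integrate_ode("base", params, T0, EMPTY, 540.0, 0.01)
        exact = logistic_history(traj.times, T0, params)
        rel = np.max(np.abs(traj.T - exact) / exact)
        assert rel < 1e-6
        assert np.all(traj.C == 0.0)

    def test_impulse_adds_dose_exactly(self, params, T0):
        # trajectories agree up to the dose time, so the stored value at the
        # dose time is exactly the undosed (left-limit) value plus the dose
        m = 1.89e8
        with_dose = integrate_ode(
            "base", params, T0, DoseSchedule([(0.0, 1e7), (14.0, m)]), 14.0, 0.01
        )
        without = integrate_ode(
            "base", params, T0, DoseSchedule([(0.0, 1e7)]), 14.0, 0.01
        )
        assert with_dose.C[-1] == without.C[-1] + m
        assert with_dose.T[-1] == without.T[-1]

    def test_tumor_continuous_across_jump(self, params, T0):
        sched = DoseSchedule([(0.0, 1e7), (14.0, 1.89e8)])
        traj = integrate_ode("resistance", params, T0, sched, 28.0, 0.01)
        k = int(round(14.0 / 0.01))
        step_drift = abs(traj.T[k - 1] - traj.T[k - 2])
        assert abs(traj.T[k] - traj.T[k - 1]) <= 1.5 * step_drift + 1.0
        assert abs(traj.R[k] - traj.R[k - 1]) <= 1.5 * abs(traj.R[k - 1] - traj.R[k - 2]) + 1e-12

    def test_impulse_additivity(self, params, T0):
        m = 2e8
        one = integrate_ode("base", params, T0, DoseSchedule([(7.0, m)]), 21.0, 0.01)
        two = integrate_ode(
            "base", params, T0, DoseSchedule([(7.0, m / 2), (7.0, m / 2)]), 21.0, 0.01
        )
        np.testing.assert_array_equal(one.C, two.C)
        np.testing.assert_array_equal(one.T, two.T)

    def test_off_grid_dose_time_rejected(self, params, T0):
        with pytest.raises(ValueError, match="not a multiple"):
            integrate_ode("base", params, T0, DoseSchedule([(0.005, 1e7)]), 10.0, 0.01)

    def test_dose_beyond_horizon_rejected(self, params, T0):
        with pytest.raises(ValueError):
            integrate_ode("base", params, T0, DoseSchedule([(50.0, 1e7)]), 10.0, 0.01)

    def test_positivity_and_r_bounds(self, params, T0):
        sched = DoseSchedule([(0.0, 5e8)] + [(7.0 * j, 1e8) for j in range(1, 10)])
        traj = integrate_ode("resistance", params, T0, sched, 120.0, 0.01)
        assert np.all(traj.T >= 0)
        assert np.all(traj.C >= 0)
        assert np.all(traj.R >= 0) and np.all(traj.R < 1.0)
        assert np.all(np.diff(traj.R) >= 0)  # R nondecreasing while C >= 0

    def test_unstable_step_aborts_with_diagnostic(self, params, T0):
        # a grossly too-large step makes the CAR-T equation blow up
        with pytest.raises(FloatingPointError):
            integrate_ode(
                "base",
                params.with_overrides(rho_C=200.0, g_C=1.0),
                T0,
                DoseSchedule([(0.0, 1e9)]),
                400.0,
                10.0,
            )

    def test_rk4_convergence_order(self, params, T0):
        sched = DoseSchedule([(0.0, 5e8)])

        def c_end(dt):
            return integrate_ode("base", params, T0, sched, 40.0, dt).C[-1]

        ref = c_end(0.0125)
        errs = [abs(c_end(dt) - ref) for dt in (0.4, 0.2)]
        order = np.log2(errs[0] / errs[1])
        assert order >= 3.5


class TestDdeIntegrator:
    def test_no_treatment_matches_logistic(self, params, T0):
        traj = integrate_dde(params, T0, EMPTY, 540.0, 0.01)
        exact = logistic_history(traj.times, T0, params)
        assert np.max(np.abs(traj.T - exact) / exact) < 1e-6
        assert np.all(traj.C == 0.0)

    def test_lag_must_divide_grid(self, params, T0):
        with pytest.raises(ValueError, match="tau"):
            integrate_dde(params.with_overrides(tau=0.015), T0, EMPTY, 10.0, 0.01)

    def test_grid_refinement_stable(self, params, T0):
        # halving the step changes the day-540 tumor burden by < 0.1%
        sched = DoseSchedule([(0.0, 5e8)])
        coarse = integrate_dde(params, T0, sched, 540.0, 0.01)
        fine = integrate_dde(params, T0, sched, 540.0, 0.005)
        assert abs(coarse.T[-1] - fine.T[-1]) / fine.T[-1] < 1e-3

    def test_rk2_convergence_order(self, params, T0):
        # smooth dose-free limit: tau = 0 reduces to the base model
        p0 = params.with_overrides(tau=0.0)
        sched = DoseSchedule([(0.0, 5e8)])

        def c_end(dt):
            return integrate_dde(p0, T0, sched, 40.0, dt).C[-1]

        ref = c_end(0.0125)
        errs = [abs(c_end(dt) - ref) for dt in (0.4, 0.2)]
        assert np.log2(errs[0] / errs[1]) >= 1.8

    def test_impulse_jump_equals_dose(self, params, T0):
        m = 1.89e8
        with_dose = integrate_dde(
            params, T0, DoseSchedule([(0.0, m), (84.0, m)]), 84.0, 0.01
        )
        without = integrate_dde(params, T0, DoseSchedule([(0.0, m)]), 84.0, 0.01)
        assert with_dose.jump_times == (0.0, 84.0)
        assert with_dose.C[-1] == without.C[-1] + m
        assert with_dose.T[-1] == without.T[-1]

    def test_schedule_shift_invariance(self, params, T0):
        """Starting the same protocol later, from the logistically grown
        tumor, shifts the whole treated trajectory in time."""
        delta = 10.0
        m = 5e8
        a = integrate_dde(params, T0, DoseSchedule([(0.0, m)]), 100.0, 0.01)
        T0_early = float(logistic_history(-delta, T0, params))
        b = integrate_dde(
            params, T0_early, DoseSchedule([(delta, m)]), 100.0 + delta, 0.01
        )
        shift = int(round(delta / 0.01))
        np.testing.assert_allclose(b.T[shift:], a.T, rtol=1e-5)
        np.testing.assert_allclose(
            b.C[shift:], a.C, rtol=1e-4, atol=1e-6 * m
        )
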