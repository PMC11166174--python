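"""Compartment solver, frame averaging, SUV and decay correction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from maglpet import (
    FrameSchedule,
    InputFunction,
    RateConstants,
    TimeActivityCurve,
    ValidationError,
    decay_correct,
    frame_average,
    simulate_tac,
    solve_compartments,
    to_suv,
)

GRID = np.linspace(0.0, 90.0, 181)


def ivp_oracle(rc: RateConstants, inp: InputFunction, grid, y0=(0.0, 0.0, 0.0)):
    """Independent high-accuracy stiff integration of the same ODEs."""

    def rhs(t, y):
        cp = float(inp(t))
        khm = rc.kh / 60.0
        return [
            rc.K1 * cp - (rc.k2 + rc.k3) * y[0],
            rc.k3 * y[0] - khm * y[1],
            khm * y[1] - rc.k5 * y[2],
        ]

    sol = solve_ivp(rhs, (grid[0], grid[-1]), list(y0), t_eval=grid,
                    method="Radau", rtol=1e-11, atol=1e-13)
    assert sol.success
    return sol.y


class TestSolveCompartments:
    def test_null_system_stays_zero(self):
        rc = RateConstants(0, 0, 0, 0, k5=0)
        zero = InputFunction(0.0, 0.0, 1.0, 1.0)
        cc = solve_compartments(rc, zero, GRID)
        assert np.all(cc.total == 0.0)

    def test_analytic_washout_limit(self):
        # no input, unit complex, k5 = 100*K_H: C2 decays exactly as
        # exp(-K_H t) and quasi-steady CO2 adds K_H/(k5-K_H) = 1/99 of C2,
        # so total tracks exp(-K_H t) to within that ~1 % fraction
        kh = 0.62
        rc = RateConstants(K1=0.0, k2=0.3, k3=0.6, kh=kh, k5=100 * kh / 60.0)
        zero = InputFunction(0.0, 0.0, 1.0, 1.0)
        cc = solve_compartments(rc, zero, GRID, initial_state=(0.0, 1.0, 0.0))
        late = (cc.t >= 15.0)
        expected = np.exp(-kh * cc.t[late] / 60.0)
        ratio = cc.total[late] / expected
        assert np.all(ratio >= 1.0 - 1e-12)
        assert np.all(ratio <= 1.0 + 1.0 / 99.0 + 1e-9)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_stiff_integrator_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        rc = RateConstants(
            K1=rng.uniform(0.02, 0.5), k2=rng.uniform(0.05, 1.0),
            k3=rng.uniform(0.05, 1.5), kh=rng.uniform(0.1, 2.0),
            k5=rng.uniform(0.5, 3.0))
        A1 = rng.uniform(5.0, 20.0)
        # |A2| <= A1 with lam2 > lam1 keeps Cp >= 0 everywhere
        inp = InputFunction(A1, -rng.uniform(0.0, 1.0) * A1,
                            rng.uniform(0.1, 0.6), rng.uniform(2.0, 6.0))
        grid = np.linspace(0.0, 90.0, 46)
        cc = solve_compartments(rc, inp, grid)
        ref = ivp_oracle(rc, inp, grid)
        scale = np.abs(ref).max()
        assert np.abs(np.vstack([cc.C1, cc.C2, cc.C3]) - ref).max() / scale < 1e-6

    def test_piecewise_rates_switch_applies(self, default_input):
        rc = RateConstants(K1=0.1, k2=0.3, k3=0.6, kh=0.7)
        blocked = RateConstants(K1=0.1, k2=0.3, k3=0.0, kh=0.7)
        cc_chase = solve_compartments([(0.0, rc), (20.0, blocked)], default_input, GRID)
        cc_plain = solve_compartments(rc, default_input, GRID)
        pre = GRID <= 20.0
        assert np.allclose(cc_chase.total[pre], cc_plain.total[pre], rtol=1e-12)
        assert cc_chase.C2[-1] < cc_plain.C2[-1]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            RateConstants(K1=-0.1, k2=0.3, k3=0.6, kh=0.7)

    def test_non_monotone_grid_rejected(self, default_input, healthy_rates):
        with pytest.raises(ValidationError):
            solve_compartments(healthy_rates, default_input, [0.0, 10.0, 5.0])

    def test_mass_flow_non_increasing_after_input_gone(self, default_input, healthy_rates):
        grid = np.linspace(20.0, 90.0, 200)
        cc = solve_compartments(healthy_rates, default_input,
                                np.concatenate([[0.0], grid]))
        total = cc.total[1:]
        assert np.all(np.diff(total) <= 1e-12)

    def test_late_log_slope_approaches_kh(self, default_input):
        # k5/K_H = 150 (the in-vivo regime): late log-activity slope = -K_H
        k5 = 1.74
        kh = k5 * 60.0 / 150.0
        rc = RateConstants(K1=0.1, k2=0.3, k3=0.6, kh=kh, k5=k5)
        grid = np.linspace(15.0, 90.0, 151)
        cc = solve_compartments(rc, default_input, np.concatenate([[0.0], grid]))
        slope = np.polyfit(grid / 60.0, np.log(cc.total[1:]), 1)[0]
        assert abs(-slope - kh) / kh < 0.02

    def test_blocking_lowers_peak_and_washes_out(self, default_input, schedule):
        rc = RateConstants(K1=0.1075, k2=0.3, k3=0.6, kh=0.66)
        blocked = RateConstants(K1=0.1075, k2=0.3, k3=0.0, kh=0.66)
        tac = simulate_tac(rc, default_input, schedule)
        tac_b = simulate_tac(blocked, default_input, schedule)
        assert tac_b.values.max() < tac.values.max()
        assert tac_b.values[-1] < 0.05 * tac_b.values.max()

    def test_chase_barely_changes_late_curve_once_trapped(self, default_input, schedule):
        rc = RateConstants(K1=0.1075, k2=0.3, k3=0.6, kh=0.66)
        cc = solve_compartments(rc, default_input, np.array([0.0, 20.0]))
        assert cc.C1[-1] < 0.05 * cc.total[-1]  # free pool is gone by 20 min
        chase = [(0.0, rc), (20.0, RateConstants(K1=0.1075, k2=0.3, k3=0.0, kh=0.66))]
        tac = simulate_tac(rc, default_input, schedule)
        tac_c = simulate_tac(chase, default_input, schedule)
        late = schedule.midpoints >= 20.0
        rel = np.abs(tac_c.values[late] - tac.values[late]) / tac.values[late]
        assert rel.max() < 0.05


class TestFrameAverage:
    def test_constant_signal(self, schedule):
        tac = frame_average(lambda t: 2.0, schedule)
        assert np.allclose(tac.values, 2.0)

    def test_linear_ramp_gives_midpoints(self, schedule):
        tac = frame_average(lambda t: t, schedule)
        assert np.allclose(tac.values, schedule.midpoints, atol=1e-10)

    def test_exponential_matches_closed_form(self, schedule):
        lam = 0.05
        tac = frame_average(lambda t: np.exp(-lam * t), schedule)
        a, b = schedule.start, schedule.end
        exact = (np.exp(-lam * a) - np.exp(-lam * b)) / (lam * (b - a))
        assert np.abs(tac.values - exact).max() < 1e-8

    def test_simulate_tac_equals_quadrature_of_evaluator(self, default_input, schedule):
        rc = RateConstants(K1=0.1, k2=0.3, k3=0.6, kh=0.7)
        exact = simulate_tac(rc, default_input, schedule)
        cc = solve_compartments(rc, default_input, np.linspace(0, 90, 10))
        quad_tac = frame_average(cc, schedule)
        assert np.allclose(exact.values, quad_tac.values, atol=1e-8)


class TestSuvAndDecay:
    @pytest.mark.parametrize("conc,expected", [(50.0, 1.0), (0.0, 0.0), (100.0, 2.0)])
    def test_suv_definition(self, conc, expected):
        # dose/weight = 50, so a concentration of 50 is SUV 1
        assert to_suv(conc, injected_dose=10.0, body_weight=0.2) == pytest.approx(expected)

    def test_suv_rejects_nonpositive_inputs(self):
        with pytest.raises(ValidationError):
            to_suv(1.0, 0.0, 0.2)
        with pytest.raises(ValidationError):
            to_suv(1.0, 10.0, -1.0)

    def test_decay_correction_round_trip(self, schedule, rng):
        tac = TimeActivityCurve(schedule, rng.uniform(0.5, 2.0, len(schedule)))
        corrected = decay_correct(tac)
        back = decay_correct(corrected, invert=True)
        assert np.allclose(back.values, tac.values, atol=1e-12)

    def test_reference_frame_unchanged(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(len(schedule)))
        ref = schedule.midpoints[5]
        corrected = decay_correct(tac, reference_time=ref)
        assert corrected.values[5] == pytest.approx(1.0)

    def test_one_half_life_doubles(self, schedule):
        # constant true activity measured as decaying counts: correcting a
        # frame one half-life after reference doubles the measured value
        half_life = 20.4
        measured = 2.0 ** (-schedule.midpoints / half_life)
        corrected = decay_correct(TimeActivityCurve(schedule, measured), half_life)
        assert np.allclose(corrected.values, 1.0, atol=1e-12)


class TestTypes:
    def test_default_schedule_shape(self, schedule):
        assert len(schedule) == 26
        assert schedule.start[0] == 0.0 and schedule.end[-1] == 90.0
        assert np.allclose(schedule.durations[:4], 1.0)
        assert np.allclose(schedule.durations[4:12], 2.0)
        assert np.allclose(schedule.durations[12:], 5.0)

    def test_schedule_rejects_gaps_and_zero_frames(self):
        with pytest.raises(ValidationError):
            FrameSchedule([0.0, 2.0], [1.0, 3.0])  # gap between frames
        with pytest.raises(ValidationError):
            FrameSchedule([0.0, 1.0], [1.0, 1.0])  # zero duration

    def test_tac_length_and_finiteness(self, schedule):
        with pytest.raises(ValidationError):
            TimeActivityCurve(schedule, np.ones(25))
        bad = np.ones(26)
        bad[3] = np.nan
        with pytest.raises(ValidationError):
            TimeActivityCurve(schedule, bad)

    def test_kh_unit_round_trip(self):
        rc = RateConstants(K1=0.1, k2=0.3, k3=0.6, kh=0.66)
        assert rc.kh == pytest.approx(60.0 * rc.kh_per_min)
        assert rc.with_kh_per_min(rc.kh_per_min).kh == pytest.approx(rc.kh)

    def test_input_function_nonnegativity_enforced(self):
        with pytest.raises(ValidationError):
            InputFunction(1.0, -2.0, 0.4, 4.0)  # dips negative at late times
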