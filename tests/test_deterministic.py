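"""ODE engine, dose-response/EC analysis, sensitivity, and the
cyclin D1 steady-state scan."""

import numpy as np
import pytest

from gliodiff.deterministic import (
    DoseResponseCurve,
    NonMonotoneResponseError,
    apparent_hill,
    basal_steady_state,
    cyclind1_degradation_slope,
    cyclind1_steady_states,
    dose_response,
    ec_quantile,
    sensitivity_timecourse,
    solve_ode,
    time_averaged_sensitivity,
)
from gliodiff.model import SPECIES, default_parameters


class TestSolveOde:
    def test_equilibrium_stays_put(self, params, basal):
        traj = solve_ode(params, basal, CT=0.0, T=48.0)
        assert np.max(np.abs(traj.states - basal)) < 1e-6

    def test_tolerance_refinement_converges(self, params, basal):
        grid = np.array([0.0, 48.0])
        a = solve_ode(params, basal, 10.0, 48.0, grid=grid, rtol=1e-8).states[-1]
        b = solve_ode(params, basal, 10.0, 48.0, grid=grid, rtol=5e-9).states[-1]
        assert np.max(np.abs(a - b)) < 1e-6

    def test_pka_matches_linear_closed_form(self):
        # with n1=1 PKA is linear: a1/d1 + (V1 H(CT)/d1)(1 - e^(-d1 t))
        p = default_parameters().with_updates(n1=1.0, K1=5.0, V1=1.0, a1=0.1, d1=1.0)
        y0 = np.zeros(10)
        y0[0] = 0.1
        traj = solve_ode(p, y0, CT=10.0, T=12.0, rtol=1e-10)
        H = 10.0 / 15.0
        expected = 0.1 + H * (1.0 - np.exp(-traj.t))
        assert np.max(np.abs(traj.species("PKA") - expected)) < 1e-6

    def test_rejects_nonpositive_horizon(self, params, basal):
        with pytest.raises(ValueError):
            solve_ode(params, basal, 0.0, T=0.0)


class TestEcQuantile:
    def _curve(self, x, y):
        return DoseResponseCurve(doses=x, response=y, species="GFAP", t_read=48.0)

    def test_linear_ramp_is_identity(self):
        x = np.linspace(0, 1, 201)
        c = self._curve(x, x)
        assert ec_quantile(c, 0.1) == pytest.approx(0.1, abs=1e-3)
        assert ec_quantile(c, 0.9) == pytest.approx(0.9, abs=1e-3)

    # n >= 2 keeps the finite log-dose window's truncation bias of the
    # baseline/saturation levels below the assertion tolerance
    @pytest.mark.parametrize("n", [2.0, 4.0, 6.0])
    def test_exact_hill_ratio_identity(self, n):
        x = np.logspace(-3, 3, 4001)
        c = self._curve(x, x**n / (1.0 + x**n))
        ratio = ec_quantile(c, 0.9) / ec_quantile(c, 0.1)
        assert ratio == pytest.approx(81.0 ** (1.0 / n), rel=1e-3)

    def test_decreasing_curve_uses_fractional_decrease(self):
        x = np.linspace(0, 1, 201)
        c = self._curve(x, 1.0 - x)
        assert ec_quantile(c, 0.9) == pytest.approx(0.9, abs=1e-3)

    def test_out_of_range_quantile_rejected(self):
        x = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            ec_quantile(self._curve(x, x), 1.5)

    def test_non_monotone_curve_refused(self):
        x = np.linspace(0, 1, 101)
        y = np.sin(3 * x)
        with pytest.raises(NonMonotoneResponseError):
            ec_quantile(self._curve(x, y), 0.5)


class TestApparentHill:
    def test_exact_hill_curve_recovers_exponent(self):
        x = np.logspace(-2, 2, 4001)
        c = DoseResponseCurve(
            doses=x, response=x**4 / (1.0 + x**4), species="GFAP", t_read=48.0
        )
        assert apparent_hill(c) == pytest.approx(4.0, rel=1e-3)

    def test_linear_ramp_gives_two(self):
        x = np.linspace(0.0, 1.0, 2001)
        c = DoseResponseCurve(doses=x, response=x, species="GFAP", t_read=48.0)
        # EC90/EC10 = 9 for a ramp through zero, and ln81/ln9 = 2
        assert apparent_hill(c) == pytest.approx(2.0, rel=1e-3)


class TestDoseResponse:
    def test_single_dose_rejected(self, params):
        with pytest.raises(ValueError):
            dose_response(params, [5.0])

    def test_gfap_nondecreasing_cyclin_nonincreasing(self, params, basal):
        doses = np.array([0.0, 3.0, 6.0, 6.5, 7.0, 10.0])
        gfap = dose_response(params, doses, "GFAP", 48.0, initial=basal)
        cyc = dose_response(params, doses, "CyclinD1", 48.0, initial=basal)
        assert np.all(np.diff(gfap.response) >= -1e-9)
        assert np.all(np.diff(cyc.response) <= 1e-9)


class TestSensitivity:
    def test_constant_timecourse_average(self):
        assert time_averaged_sensitivity(np.full(50, -3.0)) == pytest.approx(3.0)
        assert np.isnan(time_averaged_sensitivity(np.full(3, np.nan)))

    def test_decoupled_parameter_has_zero_sensitivity(self, params):
        # with the CREB/STAT3 arm switched off, CREB kinetics cannot
        # influence GFAP at all
        p = params.with_updates(V10ab=0.0)
        _, S, _ = sensitivity_timecourse(p, "V2", CT=10.0, T=12.0, L=25)
        assert np.nanmax(np.abs(S)) < 1e-6

    def test_zero_baseline_points_are_reported(self, params, basal):
        # no production at all: GFAP decays from 0 and stays 0
        p = params.with_updates(V10ab=0.0, V10c=0.0)
        y0 = basal.copy()
        y0[9] = 0.0
        _, S, excluded = sensitivity_timecourse(
            p, "d10", CT=0.0, T=6.0, L=10, initial=y0
        )
        assert excluded == 10
        assert np.all(np.isnan(S))


class TestCyclinSteadyStates:
    def test_zero_is_always_a_root(self, params):
        roots = cyclind1_steady_states(params, aGSK3b_level=0.5)
        assert roots[0][0] == 0.0

    def test_three_roots_in_bistable_regime(self):
        # effective degradation slope g = 0.1 with V6=1, K6a=0.5, n2=4:
        # roots near 0, ~0.19 and just below V6/g = 10
        p = default_parameters().with_updates(
            V6=1.0, K6a=0.5, n2=4.0, d6=0.2, K6b=1.0, GSK3bT=1.0
        )
        assert cyclind1_degradation_slope(p, 1.0) == pytest.approx(0.1)
        roots = cyclind1_steady_states(p, 1.0)
        values = [r for r, _ in roots]
        stability = [s for _, s in roots]
        assert len(values) == 3
        assert values[0] == 0.0
        assert values[1] == pytest.approx(0.189, abs=5e-3)
        assert 9.9 < values[2] < 10.0
        assert stability == [True, False, True]

    def test_single_root_above_fold(self):
        # g far above the fold threshold: only extinction remains
        p = default_parameters().with_updates(
            V6=1.0, K6a=0.5, n2=4.0, d6=3.0, K6b=0.1, GSK3bT=1.0
        )
        roots = cyclind1_steady_states(p, 1.0)
        assert [r for r, _ in roots] == [0.0]

    def test_matches_dense_grid_enumeration(self):
        """Scanner agrees with brute-force sign-change enumeration on a
        10^4-point grid for randomized parameter draws."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = default_parameters().with_updates(
                V6=rng.uniform(0.2, 2.0),
                K6a=rng.uniform(0.2, 1.5),
                n2=float(rng.integers(2, 6)),
                d6=rng.uniform(0.1, 2.0),
                K6b=rng.uniform(0.1, 2.0),
            )
            aG = rng.uniform(0.1, 1.0)
            g = cyclind1_degradation_slope(p, aG)
            xs = np.linspace(0.0, p.V6 / g * 1.05 + p.K6a, 10001)
            fs = p.V6 * xs**p.n2 / (p.K6a**p.n2 + xs**p.n2) - g * xs
            brute = [0.0] + [
                0.5 * (xs[i] + xs[i + 1])
                for i in range(1, len(xs) - 1)
                if fs[i] * fs[i + 1] < 0
            ]
            found = [r for r, _ in cyclind1_steady_states(p, aG)]
            assert len(found) == len(brute)
            dx = xs[1] - xs[0]
            for b, f in zip(brute, found):
                assert abs(b - f) <= dx

    def test_long_time_dose_response_agrees_with_steady_states(self, params, basal):
        """After long treatment, cyclin D1 sits on a fixed point of the
        scan evaluated at the treated aGSK3b level."""
        y = solve_ode(params, basal, 10.0, 600.0, grid=np.array([0.0, 600.0])).states[-1]
        aG = params.GSK3bT - y[SPECIES.index("pGSK3b")]
        roots = [r for r, stable in cyclind1_steady_states(params, aG) if stable]
        assert min(abs(y[SPECIES.index("CyclinD1")] - r) for r in roots) < 1e-5
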