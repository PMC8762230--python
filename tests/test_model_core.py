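"""Structural-model unit tests: clearance algebra, ODE solves, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voripk import (IndividualParams, Regimen, SolverError, bateman_oracle,
                    bateman_superposition, mosteller_bsa, nonlinear_clearance,
                    ode_rhs, solve_profile, typical_vmax)
from voripk.model_core import SystemState


def _linear_params(CL=7.0, V1=207.29):
    """Parameters in the linear limit: the saturable pathway is off."""
    return IndividualParams(V1=V1, CL1=CL, CL2=4.65, Vmax=0.0, F=0.895,
                            ka=1.1, V2=10.01, Km=1.15, Imax=0.75, IC50=14.6)


class TestNonlinearClearance:
    def test_half_saturation_point(self, fixed):
        p = IndividualParams.typical(fixed)
        # C1 = Km halves the Vmax/Km intrinsic clearance: 18.80/2.30
        assert nonlinear_clearance(1.15, 0.0, p) == pytest.approx(8.1739, abs=1e-4)

    def test_metabolite_inhibition_limits(self, fixed):
        p = IndividualParams.typical(fixed)
        base = nonlinear_clearance(1.0, 0.0, p)
        # at C2 = IC50 the inhibition factor is exactly 1 - Imax/2
        assert nonlinear_clearance(1.0, 14.6, p) == pytest.approx(base * 0.625)
        # saturating metabolite leaves 1 - Imax of the uninhibited clearance
        assert nonlinear_clearance(1.0, 1e9, p) == pytest.approx(base * 0.25,
                                                                 rel=1e-6)

    @given(c1=st.floats(0.0, 50.0), c2=st.floats(0.0, 50.0),
           dc=st.floats(0.01, 10.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_both_concentrations(self, c1, c2, dc):
        p = _default_params()
        assert nonlinear_clearance(c1 + dc, c2, p) < nonlinear_clearance(c1, c2, p)
        assert nonlinear_clearance(c1, c2 + dc, p) < nonlinear_clearance(c1, c2, p)

    def test_negative_concentration_rejected(self, fixed):
        p = IndividualParams.typical(fixed)
        with pytest.raises(ValueError):
            nonlinear_clearance(-0.1, 0.0, p)
        with pytest.raises(ValueError):
            nonlinear_clearance(0.1, -1.0, p)


def _default_params():
    from voripk import reference_fixed_effects
    return IndividualParams.typical(reference_fixed_effects())


class TestTypicalVmax:
    @pytest.mark.parametrize("phenotype,expected", [
        ("NM", 18.80), ("IM", 13.788803), ("PM", 10.215665)])
    def test_phenotype_adjustment(self, fixed, phenotype, expected):
        assert typical_vmax(18.80, phenotype, fixed) == pytest.approx(expected,
                                                                      abs=5e-3)

    def test_unknown_phenotype_is_the_callers_problem(self, fixed):
        with pytest.raises(ValueError, match="phenotype"):
            typical_vmax(18.80, "UM", fixed)


class TestOdeRhs:
    def test_origin_is_an_equilibrium(self, fixed):
        p = IndividualParams.typical(fixed)
        assert np.all(ode_rhs(SystemState(), p) == 0.0)

    def test_absorption_inflow(self, fixed):
        p = IndividualParams.typical(fixed)
        d = ode_rhs(SystemState(A_gut=200.0), p)
        assert d[1] == pytest.approx(0.895 * 200 * 1.1)  # 196.9 mg/h
        assert d[0] == pytest.approx(-1.1 * 200)

    def test_conversion_conserves_amount(self, fixed):
        # with kn=1 and no elimination, d(A1+A2)/dt equals the gut outflow
        p = IndividualParams(V1=fixed.V1, CL1=1e-12, CL2=1e-12, Vmax=18.8,
                             F=fixed.F, ka=fixed.ka, V2=fixed.V2, Km=fixed.Km,
                             Imax=fixed.Imax, IC50=fixed.IC50, kn=1.0)
        d = ode_rhs(SystemState(A_gut=100.0, A1=50.0, A2=5.0), p)
        assert d[1] + d[2] == pytest.approx(0.895 * 1.1 * 100.0, rel=1e-9)


class TestSolveProfile:
    def test_no_elimination_retains_absorbed_dose(self, fixed):
        p = IndividualParams(V1=fixed.V1, CL1=1e-12, CL2=4.65, Vmax=0.0,
                             F=0.895, ka=1.1, V2=10.01, Km=1.15,
                             Imax=0.75, IC50=14.6)
        reg = Regimen(doses=(  # one 200 mg dose
            __import__("voripk").DoseEvent(0.0, 200.0),))
        prof = solve_profile(reg, p, [200.0])
        assert prof.C1[0] * p.V1 == pytest.approx(0.895 * 200, rel=1e-6)

    def test_linear_limit_matches_bateman_superposition(self):
        p = _linear_params()
        reg = Regimen.bid(200, 7)
        times = np.linspace(0.5, 7 * 24.0, 50)
        prof = solve_profile(reg, p, times)
        ref = np.array([bateman_superposition(reg, t, p.F, p.ka, p.CL1, p.V1)
                        for t in times])
        assert np.max(np.abs(prof.C1 - ref) / ref) < 1e-6

    def test_superposition_doubles_with_dose(self):
        p = _linear_params()
        t = np.linspace(1, 96, 20)
        c1 = solve_profile(Regimen.bid(200, 4), p, t).C1
        c2 = solve_profile(Regimen.bid(400, 4), p, t).C1
        assert np.allclose(c2, 2 * c1, rtol=1e-7)

    def test_backends_agree(self, fixed):
        p = IndividualParams.typical(fixed, "PM")
        reg = Regimen.bid(200, 5)
        t = np.linspace(6, 120, 16)
        fast = solve_profile(reg, p, t)
        ref = solve_profile(reg, p, t, backend="lsoda")
        assert np.allclose(fast.C1, ref.C1, rtol=1e-6)
        assert np.allclose(fast.C2, ref.C2, rtol=1e-6)

    def test_mass_balance_with_unit_conversion_factor(self, fixed):
        # F * (dose released from gut) = A1 + A2 + eliminated amounts.
        # Eliminated VCZ (linear path) = CL1 * cumAUC1; eliminated VNO =
        # CL2 * cumAUC2; the converted amount moves between compartments.
        p = IndividualParams.typical(fixed)
        reg = Regimen.bid(200, 14)
        t_end = 14 * 24.0
        prof = solve_profile(reg, p, [t_end])
        st = prof.states[0]
        released = sum(a * (1 - math.exp(-p.ka * (t_end - td)))
                       for td, a in zip(reg.times, reg.amounts))
        lhs = p.F * released
        rhs = st[1] + st[2] + p.CL1 * st[3] + p.CL2 * st[4]
        assert rhs == pytest.approx(lhs, rel=1e-6)

    def test_bad_inputs_fail_loudly(self, fixed):
        p = IndividualParams.typical(fixed)
        reg = Regimen.bid(200, 1)
        with pytest.raises(ValueError):
            solve_profile(reg, p, [12.0], rtol=-1.0)
        with pytest.raises(ValueError):
            solve_profile(reg, p, [5.0, 2.0])
        with pytest.raises(ValueError):
            solve_profile(reg, p, [12.0], backend="rk2")
        # an exhausted step budget surfaces as a solver failure, never NaN
        from voripk.model_core import _simulate
        _, status = _simulate(reg.times, reg.amounts, np.array([24.0]),
                              p.as_array(), 1e-8, 1e-10, np.zeros(5), 3)
        assert status == 3

    def test_steady_state_trough_monotonicity(self, fixed):
        """Trough decreases with CL1 and Vmax, increases with dose."""
        def trough(cl1=1.91, vmax=18.8, dose=200.0):
            p = IndividualParams(V1=207.29, CL1=cl1, CL2=4.65, Vmax=vmax,
                                 F=0.895, ka=1.1, V2=10.01, Km=1.15,
                                 Imax=0.75, IC50=14.6)
            return solve_profile(Regimen.bid(dose, 10), p, [240.0]).C1[0]

        base = trough()
        assert trough(cl1=3.0) < base and trough(cl1=1.0) > base
        assert trough(vmax=25.0) < base and trough(vmax=12.0) > base
        assert trough(dose=300.0) > base > trough(dose=150.0)

    def test_saturable_elimination_makes_auc_superlinear_in_dose(self, fixed):
        """Dose-normalized steady-state AUC grows with dose."""
        p = IndividualParams.typical(fixed)
        norm_aucs = []
        for dose in (150.0, 200.0, 400.0):
            reg = Regimen.bid(dose, 10)
            prof = solve_profile(reg, p, [216.0, 240.0])
            norm_aucs.append((prof.cumAUC1[1] - prof.cumAUC1[0]) / dose)
        assert norm_aucs[0] < norm_aucs[1] < norm_aucs[2]


class TestBatemanOracle:
    def test_boundary_values(self):
        assert bateman_oracle(200, 0.0, 0.895, 1.1, 7.0, 207.0) == 0.0
        assert bateman_oracle(200, 1e6, 0.895, 1.1, 7.0, 207.0) == pytest.approx(0.0)

    def test_peak_at_analytic_tmax(self):
        F, ka, CL, V = 0.895, 1.1, 7.0, 207.0
        k = CL / V
        tmax = math.log(ka / k) / (ka - k)
        c_peak = bateman_oracle(200, tmax, F, ka, CL, V)
        for dt in (-0.5, 0.5):
            assert bateman_oracle(200, tmax + dt, F, ka, CL, V) < c_peak

    def test_absorption_equal_elimination_limit(self):
        # ka == CL/V uses the analytic limit F*D*ka*t/V * exp(-ka t)
        c = bateman_oracle(100, 2.0, 1.0, 0.5, 5.0, 10.0)
        assert c == pytest.approx(1.0 * 100 * 0.5 * 2.0 / 10.0 * math.exp(-1.0))


class TestMostellerBsa:
    @pytest.mark.parametrize("h,w,expected", [
        (170, 64, 1.738), (100, 36, 1.000), (180, 72, 1.897)])
    def test_worked_values(self, h, w, expected):
        assert mosteller_bsa(h, w) == pytest.approx(expected, abs=5e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            mosteller_bsa(0, 64)
        with pytest.raises(ValueError):
            mosteller_bsa(170, -1)


class TestRegimen:
    def test_bid_tid_schedules(self):
        bid = Regimen.bid(200, 2)
        assert list(bid.times) == [0, 12, 24, 36]
        tid = Regimen.tid(150, 1)
        assert list(tid.times) == [0, 8, 16]

    def test_loading_phase(self):
        reg = Regimen.bid(200, 2, loading_amount=400, n_loading=2)
        assert list(reg.amounts) == [400, 400, 200, 200]
        assert list(reg.times) == [0, 12, 24, 36]

    def test_nonincreasing_times_rejected(self):
        from voripk import DoseEvent
        with pytest.raises(ValueError):
            Regimen(doses=(DoseEvent(5.0, 100.0), DoseEvent(5.0, 100.0)))
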