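"""Electrophysiology core: currents, gating, derivatives, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cardioec import _kernels as K
from cardioec import registry as R
from cardioec.disease import ImpactFactors, factors_for_case
from cardioec.gpb import (compute_currents, derivatives, late_na_current,
                          late_na_gate_rates, nernst, total_calcium,
                          validate_state, zero_sarcolemmal_ca_fluxes)
from cardioec.parameters import GPBParameters
from cardioec.simulation import SolverOptions, StimulusProtocol, simulate_myocyte

P = GPBParameters()
UNITY = ImpactFactors()


def _integrate(y0, t_end, params=P, factors=UNITY, stim_fn=None,
               rtol=1e-9, atol=1e-12, t_eval=None):
    """Direct stiff integration of the coupled right-hand side."""
    from cardioec.parameters import NHSParameters
    p, f, n = params.to_array(), factors.to_array(), NHSParameters().to_array()

    def rhs(t, y):
        stim = stim_fn(t) if stim_fn is not None else 0.0
        return K.full_rhs(y, p, f, n, stim, 1.0, 0.0)

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol,
                    atol=atol, t_eval=t_eval)
    assert sol.success, sol.message
    return sol


class TestLateNaCurrent:
    def test_zero_driving_force(self):
        i_j, i_sl, i_tot = late_na_current(-30.0, 0.7, 0.4, P, -30.0, -30.0)
        assert i_j == i_sl == i_tot == 0.0

    def test_closed_activation_gate(self):
        assert late_na_current(40.0, 0.0, 1.0, P, 70.0, 65.0) == (0, 0, 0)

    def test_hand_evaluated_point(self):
        # independent arithmetic: 0.11*0.0065*0.5^3*0.5*(-20-70) etc.
        i_j, i_sl, i_tot = late_na_current(-20.0, 0.5, 0.5, P, 70.0, 65.0)
        assert i_j == pytest.approx(-4.021875e-3, rel=1e-12)
        assert i_sl == pytest.approx(-3.0732813e-2, rel=1e-7)
        assert i_tot == pytest.approx(i_j + i_sl, rel=0, abs=0)

    def test_factor_scales_conductance(self):
        base = late_na_current(-20.0, 0.5, 0.5, P, 70.0, 65.0)[2]
        double = late_na_current(-20.0, 0.5, 0.5, P, 70.0, 65.0, f_NaL=2.0)[2]
        assert double == pytest.approx(2 * base, rel=1e-14)

    def test_nonfinite_vm_rejected(self):
        with pytest.raises(ValueError):
            late_na_current(np.nan, 0.5, 0.5, P, 70.0, 65.0)

    def test_current_reverses_at_nernst_potential(self):
        e_j = nernst(1, P.Nao, 9.0)
        above = late_na_current(e_j + 1, 0.5, 0.5, P, e_j, e_j)[2]
        below = late_na_current(e_j - 1, 0.5, 0.5, P, e_j, e_j)[2]
        at = late_na_current(e_j, 0.5, 0.5, P, e_j, e_j)[2]
        assert at == 0.0 and above > 0 > below


class TestLateNaGates:
    def test_removable_singularity_limit(self):
        a, b, hinf, tau = late_na_gate_rates(-47.13, P)
        assert a == pytest.approx(0.32 / 0.1, rel=1e-9)

    def test_rates_continuous_across_singularity(self):
        a0 = late_na_gate_rates(-47.13, P)[0]
        for dv in (-1e-3, 1e-3):
            assert late_na_gate_rates(-47.13 + dv, P)[0] == pytest.approx(
                a0, rel=1e-3)

    def test_inactivation_midpoint_and_bounds(self):
        assert late_na_gate_rates(-91.0, P)[2] == pytest.approx(0.5)
        for vm in np.linspace(-120, 60, 37):
            hinf = late_na_gate_rates(vm, P)[2]
            assert 0.0 < hinf < 1.0
        # steady-state inactivation decreases with depolarization
        assert late_na_gate_rates(-100.0, P)[2] > late_na_gate_rates(-60.0, P)[2]

    def test_impact_factor_scales_time_constant(self):
        assert late_na_gate_rates(-80.0, P, f_hl=2.0)[3] == pytest.approx(466.0)
        assert late_na_gate_rates(-80.0, P, f_hl=1.0)[3] == pytest.approx(233.0)


class TestCurrents:
    def setup_method(self):
        self.y = R.default_initial_state()

    def test_zero_to_multiplier_kills_transient_outward(self):
        cur = compute_currents(self.y, P, UNITY.replace(f_to=0.0))
        assert cur.I_tos == 0.0 and cur.I_tof == 0.0 and cur.I_to == 0.0

    def test_sr_leak_scales_linearly(self):
        base = compute_currents(self.y, P, UNITY).J_SRleak
        doubled = compute_currents(self.y, P, UNITY.replace(f_SRleak=2.0))
        assert doubled.J_SRleak == pytest.approx(2 * base, rel=1e-14)

    def test_pump_current_positive_and_ncx_finite_at_rest(self):
        cur = compute_currents(self.y, P, UNITY)
        assert cur.I_nak > 0
        assert np.isfinite(cur.I_ncx)

    def test_nak_matches_independent_formula(self):
        """Pointwise oracle: re-derive the Na/K pump current by hand."""
        cur = compute_currents(self.y, P, UNITY)
        vm = self.y[R.S_VM]
        FoRT = 96485.0 / (8314.0 * 310.0)
        sigma = (np.exp(140.0 / 67.3) - 1.0) / 7.0
        fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vm * FoRT)
                      + 0.0365 * sigma * np.exp(-vm * FoRT))
        expected = sum(
            frac * 1.8 * fnak * 5.4 / (1 + (11.0 / na) ** 4) / (5.4 + 1.5)
            for frac, na in ((0.11, self.y[R.S_NAJ]), (0.89, self.y[R.S_NASL])))
        assert cur.I_nak == pytest.approx(expected, rel=1e-12)

    def test_inward_rectifier_matches_independent_formula(self):
        cur = compute_currents(self.y, P, UNITY)
        vm = self.y[R.S_VM]
        ek = (8314.0 * 310.0 / 96485.0) * np.log(5.4 / self.y[R.S_KI])
        aki = 1.02 / (1 + np.exp(0.2385 * (vm - ek - 59.215)))
        bki = ((0.49124 * np.exp(0.08032 * (vm + 5.476 - ek))
                + np.exp(0.06175 * (vm - ek - 594.31)))
               / (1 + np.exp(-0.5143 * (vm - ek + 4.753))))
        expected = 0.35 * (aki / (aki + bki)) * (vm - ek)
        assert cur.I_ki == pytest.approx(expected, rel=1e-12)

    def test_total_late_na_is_sum_of_parts(self):
        y = self.y.copy()
        y[R.S_ML], y[R.S_HL] = 0.3, 0.4
        cur = compute_currents(y, P, UNITY)
        assert cur.I_NaL == cur.I_NaL_junc + cur.I_NaL_sl

    def test_invalid_state_names_offender(self):
        y = self.y.copy()
        y[R.S_M] = 1.5
        with pytest.raises(ValueError, match="m"):
            compute_currents(y, P, UNITY)
        y = self.y.copy()
        y[R.S_CAI] = -1e-5
        with pytest.raises(ValueError, match="Cai"):
            compute_currents(y, P, UNITY)


HH_GATES = ["m", "h", "j", "d", "f", "xtos", "ytos", "xtof", "ytof",
            "xkr", "xks", "mL", "hL", "fcaBj", "fcaBsl"]


class TestDerivatives:
    @settings(max_examples=40, derandomize=True)
    @given(vm=st.floats(-95, 50), gate=st.sampled_from(HH_GATES),
           g=st.floats(0.05, 0.95))
    def test_gate_relaxation_form(self, vm, gate, g):
        """Every gate obeys dg/dt = (g_inf - g)/tau: affine in g with a
        fixed point inside [0, 1]."""
        y = R.default_initial_state()
        y[R.S_VM] = vm
        idx = R.STATE_INDEX[gate]

        def dgate(val):
            yy = y.copy()
            yy[idx] = val
            return derivatives(0.0, yy, P, UNITY)[idx]

        d0, d1, dg = dgate(0.0), dgate(1.0), dgate(g)
        assert d0 >= 0.0 and d1 <= 0.0       # fixed point within [0, 1]
        assert dg == pytest.approx((1 - g) * d0 + g * d1, rel=1e-9, abs=1e-12)
        assert np.sign(dgate(0.999) - dgate(0.001)) <= 0  # relaxation slope

    def test_registry_counts_match_model_convention(self):
        assert R.N_STATES == (R.N_GPB_ORIGINAL_ODES + 1  # clamped K+
                              + R.N_LATE_NA_ODES + R.N_NHS_ODES)
        y = R.default_initial_state()
        validate_state(y)
        dy = derivatives(0.0, y, P, UNITY)
        assert dy[R.STATE_INDEX["Ki"]] == 0.0
        assert np.all(np.isfinite(dy))

    def test_stimulus_enters_membrane_equation_additively(self):
        y = R.default_initial_state()
        d0 = derivatives(0.0, y, P, UNITY, stim=0.0)
        d1 = derivatives(0.0, y, P, UNITY, stim=9.5)
        assert d1[R.S_VM] - d0[R.S_VM] == pytest.approx(9.5, rel=1e-12)
        assert d1[:R.S_VM] == pytest.approx(d0[:R.S_VM], rel=0, abs=0)

    def test_total_calcium_conserved_without_sarcolemmal_fluxes(self):
        """With every transmembrane Ca pathway zeroed, the volume-weighted
        total of free + buffered Ca across all compartments is a constant
        of motion, even through a stimulated beat."""
        params = zero_sarcolemmal_ca_fluxes(P)
        y0 = R.default_initial_state()
        stim = lambda t: 9.5 if t < 5.0 else 0.0
        sol = _integrate(y0, 300.0, params=params, stim_fn=stim,
                         t_eval=np.linspace(0, 300, 7))
        totals = np.array([total_calcium(sol.y[:, k], params)
                           for k in range(sol.y.shape[1])])
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-7

    def test_quiescent_steady_state_has_vanishing_derivatives(self):
        """A long unstimulated integration settles to a fixed point."""
        y0 = R.default_initial_state()
        from cardioec.parameters import NHSParameters
        sol = _integrate(y0, 500_000.0, rtol=1e-8, atol=1e-11,
                         t_eval=[500_000.0])
        y_ss = sol.y[:, -1]
        dy = K.full_rhs(y_ss, P.to_array(), UNITY.to_array(),
                        NHSParameters().to_array(), 0.0, 1.0, 0.0)
        scaled = np.abs(dy) / np.maximum(np.abs(y_ss), 1e-6)
        assert np.max(scaled) < 1e-7

    def test_solver_oracle_equivalence_one_beat(self):
        """One paced beat at loose vs tight tolerances agrees on Vm to
        better than 0.1 mV in max norm."""
        prot = StimulusProtocol(n_prepace=0)
        traces = [simulate_myocyte("A", prot,
                                   SolverOptions(rtol=rt, atol=at))
                  for rt, at in ((1e-6, 1e-9), (1e-9, 1e-12))]
        assert np.max(np.abs(traces[0].vm - traces[1].vm)) < 0.1

    def test_trajectories_stay_in_bounds_over_ten_beats(self):
        prot = StimulusProtocol(n_prepace=0, n_record=10)
        tr = simulate_myocyte("D", prot, SolverOptions(rtol=1e-6, atol=1e-9),
                              record_states=True)
        lo, hi = R.state_bounds()
        states = tr.states
        assert np.all(states >= lo - 1e-9) and np.all(states <= hi + 1e-9)
        for name in ("Naj", "Nasl", "Nai", "Ki", "Caj", "Casl", "Cai",
                     "Ca_sr"):
            assert np.all(states[:, R.STATE_INDEX[name]] > 0)
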