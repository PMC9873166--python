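"""Smoothed-model analytics: steady state, stability, onset, integration."""

import math

import numpy as np
import pytest
from scipy.signal import find_peaks

from hbcycle import (
    PatientParams,
    TreatmentParams,
    characteristic_function,
    hill_response,
    onset_margin,
    simulate_smoothed,
    stability,
    steady_state,
)


class TestSteadyState:
    def test_reference_fixed_point(self, patient, treatment):
        st = steady_state(patient, treatment)
        assert st.feasible
        assert st.E == pytest.approx(0.25, abs=1e-12)
        assert st.e_star == pytest.approx(0.75 / math.sqrt(3.0), rel=1e-12)
        assert st.x_star == pytest.approx(0.36 * 14.0 * 0.75 / math.sqrt(3.0), rel=1e-12)
        assert st.h_star == treatment.h_bar
        assert hill_response(st.e_star, patient) == pytest.approx(st.E, abs=1e-12)

    def test_long_rbc_lifespan_needs_no_esa(self, treatment):
        # T_RBC = 120 d > h_bar/lambda = 105 d
        st = steady_state(PatientParams(eta=1 / 120), treatment)
        assert not st.feasible and st.infeasibility_reason == "no_ESA_needed"

    def test_short_rbc_lifespan_unreachable(self, treatment):
        # T_RBC = 20 d < h_bar/(mu+lambda) = 26.25 d
        st = steady_state(PatientParams(eta=1 / 20), treatment)
        assert not st.feasible and st.infeasibility_reason == "target_unreachable"

    def test_feasibility_boundaries(self, treatment):
        eps = 1e-9
        assert steady_state(PatientParams(eta=1 / (105 - eps)), treatment).feasible
        assert not steady_state(PatientParams(eta=1 / (105 + eps)), treatment).feasible
        assert steady_state(PatientParams(eta=1 / (26.25 + 1e-6)), treatment).feasible

    def test_dose_monotone_in_lifespan_and_responsiveness(self, patient, treatment):
        x_by_trbc = [steady_state(PatientParams(eta=1 / T), treatment).x_star
                     for T in (30, 45, 60, 75, 90)]
        assert np.all(np.diff(x_by_trbc) < 0)
        x_by_mu = [steady_state(PatientParams(mu=m), treatment).x_star
                   for m in (0.2, 0.3, 0.5, 0.8)]
        assert np.all(np.diff(x_by_mu) < 0)


class TestStability:
    def test_restoring_force_coefficient(self, patient, treatment):
        st = steady_state(patient, treatment)
        sb = stability(patient, treatment, st)
        # independent route: numerical derivative of the Hill response
        de = 1e-7
        num = (hill_response(st.e_star + de, patient)
               - hill_response(st.e_star - de, patient)) / (2 * de)
        assert sb.mu_prime == pytest.approx(patient.mu * num, rel=1e-6)
        assert sb.beta == pytest.approx(sb.mu_prime * 1.0 / (0.5 * 14.0 ** 2), rel=1e-12)
        assert sb.gamma == pytest.approx(treatment.kappa * patient.eta
                                         - sb.beta * patient.tau, rel=1e-12)

    def test_delay_free_limit_is_damped(self, treatment):
        p = PatientParams(tau=1e-9)
        sb = stability(p, treatment)
        assert sb.gamma == pytest.approx(treatment.kappa * p.eta, rel=1e-6)
        assert not sb.cycling_predicted

    def test_exact_root_annihilates_chi(self, patient, treatment):
        for Trbc in (40, 60, 80):
            for Tesa in (0.7, 1.925, 4.0):
                p = PatientParams(eta=1 / Trbc)
                t = TreatmentParams(kappa=math.log(2) / Tesa)
                sb = stability(p, t)
                assert sb.residual < 1e-10
                chi = characteristic_function(sb.alpha_exact, sb.beta, p.tau,
                                              t.kappa, p.eta)
                assert abs(chi) < 1e-10

    def test_conjugate_pair_in_oscillatory_regime(self, patient, treatment):
        sb = stability(patient, treatment)
        assert sb.gamma ** 2 < 4 * sb.beta * sb.m
        assert sb.alpha_plus == sb.alpha_minus.conjugate()

    def test_truncated_root_tracks_exact_near_onset(self, patient):
        # the damped-oscillator roots stay within 1% of the refined roots
        # along a path toward the bifurcation, and both locate the crossing
        # of the imaginary axis at nearly the same kappa
        for kappa in (2.6, 2.0, 1.65, 1.6):
            sb = stability(patient, TreatmentParams(kappa=kappa))
            assert abs(sb.alpha_plus - sb.alpha_exact) < 0.01 * abs(sb.alpha_exact)
        sb0 = stability(patient, TreatmentParams())
        kappa_trunc = sb0.beta * patient.tau / patient.eta  # gamma = 0

        def re_exact(kappa):
            return stability(patient, TreatmentParams(kappa=kappa)).alpha_exact.real

        lo, hi = 1.2, 2.2
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if re_exact(mid) > 0 else (lo, mid)
        assert 0.5 * (lo + hi) == pytest.approx(kappa_trunc, rel=0.05)

    def test_infeasible_state_rejected(self, treatment):
        with pytest.raises(ValueError, match="feasible"):
            stability(PatientParams(eta=1 / 120), treatment)


class TestOnsetMargin:
    def test_margin_is_minus_gamma_over_tau(self, patient, treatment):
        m, flag = onset_margin(patient, treatment)
        sb = stability(patient, treatment)
        assert m == pytest.approx(-sb.gamma / patient.tau, rel=1e-12)
        assert flag == sb.cycling_predicted

    def test_infeasible_margin_is_null(self, treatment):
        assert onset_margin(PatientParams(eta=1 / 120), treatment) is None

    def test_wider_window_inhibits_cycling(self, patient):
        margins = [onset_margin(patient, TreatmentParams(h_hi=h))[0]
                   for h in (10.6, 11.0, 11.5)]
        assert np.all(np.diff(margins) < 0)

    def test_dosing_interval_enters_quadratically(self, patient):
        # beta * tau_int^2 is invariant along a tau_int sweep
        vals = []
        for ti in (7.0, 14.0, 28.0):
            t = TreatmentParams(tau_int=ti)
            vals.append(stability(patient, t).beta * ti ** 2)
        assert np.allclose(vals, vals[0], rtol=1e-12)


class TestSimulateSmoothed:
    def test_fixed_point_is_stationary(self, patient, treatment):
        st = steady_state(patient, treatment)
        t, h, x, e = simulate_smoothed(patient, treatment, span=200.0, step=0.05)
        assert np.max(np.abs(h - st.h_star)) < 1e-9
        assert np.max(np.abs(x - st.x_star)) < 1e-9

    def test_damped_regime_decay_matches_characteristic_root(self, patient):
        # stable, oscillatory regime: fitted envelope decay ~ Re(alpha_exact)
        t = TreatmentParams(kappa=2.4)
        st = steady_state(patient, t)
        sb = stability(patient, t, st)
        assert sb.gamma > 0 and sb.damped_oscillatory
        tt, h, x, e = simulate_smoothed(
            patient, t, span=3000.0, step=0.1,
            init=(st.h_star + 0.5, st.x_star, st.e_star))
        dev = np.abs(h - st.h_star)
        pk, _ = find_peaks(dev, height=1e-6)
        sel = (tt[pk] > 100) & (tt[pk] < 2500)
        slope = np.polyfit(tt[pk][sel], np.log(dev[pk][sel]), 1)[0]
        assert slope == pytest.approx(sb.alpha_exact.real, rel=0.15)

    def test_unstable_regime_saturates_in_a_bounded_cycle(self, patient, treatment):
        # the reference point is beyond the smoothed Hopf threshold
        st = steady_state(patient, treatment)
        sb = stability(patient, treatment, st)
        assert sb.cycling_predicted
        tt, h, x, e = simulate_smoothed(
            patient, treatment, span=4000.0, step=0.1,
            init=(st.h_star + 0.1, st.x_star, st.e_star))
        dev = np.abs(h - st.h_star)
        n = dev.size
        a_mid = dev[n // 2: 3 * n // 4].max()
        a_late = dev[3 * n // 4:].max()
        assert a_late > 10 * 0.1        # perturbation grew
        assert a_late < 10.0            # but saturated (phi is bounded)
        assert a_late == pytest.approx(a_mid, rel=0.25)  # amplitude settled
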