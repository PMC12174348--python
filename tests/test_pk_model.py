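"""Structural model, solvers, and analytic identities."""

import math

import numpy as np
import pytest

from csfpk.errors import ValidationError
from csfpk.pk_model import (
    DoseEvent,
    PKParameters,
    Regimen,
    auc_ratio_limit,
    build_rate_matrix,
    mass_balance,
    simulate_profile,
    terminal_half_life,
)
from conftest import random_params


class TestRateMatrix:
    def test_human_elimination_rate_constants(self, human_params):
        """Column sums are minus the per-compartment elimination rates:
        Cl/V for central (29.8/4570 ~ 6.521e-3 /h), 0 for peripheral,
        Cl/Vcsf for CSF."""
        M = build_rate_matrix(human_params)
        col_sums = M.sum(axis=0)
        assert col_sums[0] == pytest.approx(-29.8 / 4570.0)
        assert col_sums[0] == pytest.approx(-6.521e-3, rel=1e-3)
        assert col_sums[1] == pytest.approx(0.0, abs=1e-18)
        assert col_sums[2] == pytest.approx(-29.8 / 1910.0)

    def test_transfer_entries(self, human_params):
        p = human_params
        M = build_rate_matrix(p)
        assert M[1, 0] == pytest.approx(p.Cl2 / p.V)
        assert M[0, 1] == pytest.approx(p.Cl2 / p.V2)
        assert M[2, 0] == pytest.approx(p.Qcsf / p.V)
        assert M[0, 2] == pytest.approx(p.Qcsf / p.Vcsf)
        assert M[1, 2] == 0.0 and M[2, 1] == 0.0

    def test_zero_qcsf_decouples_csf(self):
        """With no serum-CSF flow, IV dosing never reaches the CSF."""
        p = PKParameters(V=100, Cl=5, V2=200, Cl2=3, Vcsf=50, Qcsf=0.0)
        M = build_rate_matrix(p)
        assert M[2, 0] == 0.0 and M[0, 2] == 0.0
        reg = Regimen.single_iv_infusion(10, 1.0, 0.5)
        prof = simulate_profile(p, reg, np.linspace(0, 100, 50))
        assert np.all(prof.csf == 0.0)
        assert prof.serum.max() > 0

    @pytest.mark.parametrize("field", ["V", "Cl", "V2", "Vcsf"])
    def test_nonpositive_parameter_named_in_error(self, field):
        values = dict(V=100, Cl=5, V2=200, Cl2=3, Vcsf=50, Qcsf=0.1)
        values[field] = 0.0
        with pytest.raises(ValidationError, match=field):
            PKParameters(**values)

    def test_parameter_roundtrip_dict(self, human_params):
        again = PKParameters.from_dict(human_params.as_dict())
        for name in PKParameters.names:
            assert getattr(again, name) == getattr(human_params, name)


class TestDoseEvents:
    def test_bolus_duration_contract(self):
        with pytest.raises(ValidationError):
            DoseEvent("iv_bolus", 100.0, 0.0, 0.5)
        with pytest.raises(ValidationError):
            DoseEvent("iv_infusion", 100.0, 0.0, 0.0)
        assert DoseEvent("iv_infusion", 100.0, 0.0, 0.5).rate == 200.0

    def test_regimen_events_must_be_sorted(self):
        events = (
            DoseEvent("iv_bolus", 1.0, 10.0),
            DoseEvent("iv_bolus", 1.0, 0.0),
        )
        with pytest.raises(ValidationError, match="sorted"):
            Regimen(events, body_weight=4.42)


class TestSimulateProfile:
    def test_zero_dose_gives_zero_profile(self, monkey_params):
        reg = Regimen.single_iv_infusion(0.0, 4.42)
        prof = simulate_profile(monkey_params, reg, np.linspace(0, 500, 100))
        assert np.all(prof.serum == 0.0) and np.all(prof.csf == 0.0)

    def test_linearity_doubling_dose(self, monkey_params):
        t = np.linspace(0, 1008, 300)
        p1 = simulate_profile(monkey_params, Regimen.single_iv_infusion(100, 4.42), t)
        p2 = simulate_profile(monkey_params, Regimen.single_iv_infusion(200, 4.42), t)
        np.testing.assert_allclose(p2.serum[1:], 2 * p1.serum[1:], rtol=1e-9)
        np.testing.assert_allclose(p2.csf[1:], 2 * p1.csf[1:], rtol=1e-9)

    def test_one_compartment_limit_matches_exponential(self):
        """Cl2 = Qcsf = 0 and an IV bolus: serum = (D/V) exp(-Cl/V t)."""
        p = PKParameters(V=120.0, Cl=3.0, V2=50.0, Cl2=0.0, Vcsf=20.0, Qcsf=0.0)
        D = 5000.0
        reg = Regimen((DoseEvent("iv_bolus", D),), body_weight=1.0)
        t = np.linspace(0, 200, 101)
        prof = simulate_profile(p, reg, t)
        expected = (D / p.V) * np.exp(-(p.Cl / p.V) * t)
        np.testing.assert_allclose(prof.serum, expected, rtol=1e-9)

    def test_closed_form_vs_ode_human_infusion(self, human_params):
        """30-min infusion on a dense grid: the exact solution and the
        adaptive integrator must agree to 1e-6 relative everywhere."""
        reg = Regimen.single_iv_infusion(40.0, 80.0, 0.5)
        t = np.linspace(0, 1000, 400)
        cf = simulate_profile(human_params, reg, t, method="closed_form")
        ode = simulate_profile(human_params, reg, t, method="ode")
        nonzero = ode.serum > 0
        np.testing.assert_allclose(cf.serum[nonzero], ode.serum[nonzero], rtol=1e-6)
        nonzero = ode.csf > 0
        np.testing.assert_allclose(cf.csf[nonzero], ode.csf[nonzero], rtol=1e-6)

    def test_closed_form_vs_ode_random_parameters(self, rng):
        """Oracle equivalence on 100 random parameter draws."""
        t = np.linspace(0, 300, 40)
        for _ in range(100):
            p = random_params(rng)
            reg = Regimen.single_iv_infusion(10.0, 1.0, 0.5)
            cf = simulate_profile(p, reg, t, method="closed_form")
            ode = simulate_profile(p, reg, t, method="ode")
            for a, b in ((cf.serum, ode.serum), (cf.csf, ode.csf)):
                # below ~1e-8 of the peak the ODE oracle's absolute
                # tolerance dominates and it stops being a 1e-6 referee
                mask = b > 1e-8 * b.max()
                np.testing.assert_allclose(a[mask], b[mask], rtol=1e-6)

    def test_superposition_of_multidose(self, monkey_params):
        """A two-dose regimen equals the sum of time-shifted single doses."""
        t = np.linspace(0, 600, 200)
        multi = Regimen(
            (
                DoseEvent("iv_infusion", 1e6, 0.0, 0.5),
                DoseEvent("iv_infusion", 2e6, 168.0, 0.5),
            ),
            body_weight=4.42,
        )
        prof = simulate_profile(monkey_params, multi, t)
        single1 = simulate_profile(
            monkey_params,
            Regimen((DoseEvent("iv_infusion", 1e6, 0.0, 0.5),), body_weight=4.42),
            prof.times,
        )
        single2 = simulate_profile(
            monkey_params,
            Regimen((DoseEvent("iv_infusion", 2e6, 168.0, 0.5),), body_weight=4.42),
            prof.times,
        )
        total = single1.serum + single2.serum
        mask = total > 0
        np.testing.assert_allclose(prof.serum[mask], total[mask], rtol=1e-9)

    def test_icv_infusion_enters_csf_first(self, monkey_params):
        reg = Regimen((DoseEvent("icv_infusion", 1000.0, 0.0, 1.0),), body_weight=4.42)
        prof = simulate_profile(monkey_params, reg, np.linspace(0, 24, 50))
        assert prof.csf.max() > prof.serum.max()

    def test_event_times_inserted_into_grid(self, monkey_params):
        reg = Regimen.single_iv_infusion(100, 4.42, 0.5)
        prof = simulate_profile(monkey_params, reg, np.array([0.0, 10.0, 100.0]))
        assert 0.5 in prof.times


class TestMassBalance:
    def test_mass_conserved_through_infusion_and_washout(self, monkey_params):
        reg = Regimen(
            (
                DoseEvent("iv_infusion", 4.42e6, 0.0, 0.5),
                DoseEvent("iv_bolus", 1e5, 24.0),
            ),
            body_weight=4.42,
        )
        report = mass_balance(monkey_params, reg, np.linspace(0, 1008, 60))
        assert report.max_relative_error <= 1e-6


class TestAucRatioLimit:
    def test_no_flow_means_no_csf_exposure(self):
        p = PKParameters(V=100, Cl=5, V2=200, Cl2=3, Vcsf=50, Qcsf=0.0)
        assert auc_ratio_limit(p) == 0.0

    def test_vanishing_clearance_limit_is_one(self):
        p = PKParameters(V=100, Cl=1e-9, V2=200, Cl2=3, Vcsf=50, Qcsf=0.5)
        assert auc_ratio_limit(p) == pytest.approx(1.0, rel=1e-8)

    def test_human_printed_value(self, human_params):
        assert auc_ratio_limit(human_params) == pytest.approx(
            0.0639 / (0.0639 + 29.8)
        )
        assert auc_ratio_limit(human_params) == pytest.approx(2.14e-3, rel=5e-3)

    def test_matches_long_horizon_trapezoid(self, monkey_params):
        """Analytic AUC-infinity ratio vs a 40-half-life bolus simulation."""
        t_half = terminal_half_life(monkey_params).hours
        t = np.linspace(0, 40 * t_half, 6000)
        reg = Regimen((DoseEvent("iv_bolus", 4.42e6, 0.0),), body_weight=4.42)
        prof = simulate_profile(monkey_params, reg, t)
        ratio = np.trapezoid(prof.csf, prof.times) / np.trapezoid(prof.serum, prof.times)
        assert ratio == pytest.approx(auc_ratio_limit(monkey_params), rel=5e-3)


class TestTerminalHalfLife:
    def test_one_compartment_closed_form(self):
        p = PKParameters(V=120.0, Cl=3.0, V2=50.0, Cl2=0.0, Vcsf=20.0, Qcsf=0.0)
        res = terminal_half_life(p, "serum")
        assert res.hours == pytest.approx(math.log(2) * p.V / p.Cl, rel=1e-12)
        assert res.method == "eigenvalue"

    @pytest.mark.parametrize("compartment", ["serum", "csf"])
    def test_human_terminal_phase_matches_eigen_oracle(self, human_params, compartment):
        """Serum and CSF share the ~384 h terminal phase; independent
        oracle: slowest eigenvalue from numpy on the hand-built matrix."""
        M = build_rate_matrix(human_params)
        lam = np.linalg.eigvals(M)
        oracle = math.log(2) / np.abs(lam).min()
        res = terminal_half_life(human_params, compartment)
        assert res.hours == pytest.approx(oracle, rel=1e-9)
        assert res.hours == pytest.approx(384.0, rel=0.01)

    def test_monkey_terminal_half_life(self, monkey_params):
        assert terminal_half_life(monkey_params).hours == pytest.approx(215.0, rel=0.01)

    def test_matches_simulated_log_slope(self, monkey_params):
        """Cross-oracle: log-linear slope on a late simulated tail."""
        t_half = terminal_half_life(monkey_params).hours
        t = np.linspace(8 * t_half, 12 * t_half, 30)
        reg = Regimen((DoseEvent("iv_bolus", 1e6, 0.0),), body_weight=4.42)
        prof = simulate_profile(monkey_params, reg, np.concatenate([[0.0], t]))
        sel = np.isin(prof.times, t)
        slope = np.polyfit(prof.times[sel], np.log(prof.serum[sel]), 1)[0]
        assert math.log(2) / -slope == pytest.approx(t_half, rel=1e-3)
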