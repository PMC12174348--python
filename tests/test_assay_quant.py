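"""Assay normalizations, 4PL calibration, and serum-CSF concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfpk.assay_quant import (
    ConcordancePair,
    FourPL,
    StandardCurve,
    concordance_stats,
    csf_serum_ratio,
    fit_4pl,
    percent_inhibition,
    percent_surface_expression,
    pseudo_concentration,
    round_half_up,
)
from csfpk.errors import CalibrationError, ValidationError
from csfpk.reference import PATIENT_PANEL


class TestPercentNormalizations:
    @pytest.mark.parametrize(
        "sample,expected", [(500.0, 100.0), (20.0, 0.0), (260.0, 50.0)]
    )
    def test_surface_expression_anchors(self, sample, expected):
        res = percent_surface_expression(sample, mfi_100=500.0, mfi_0=20.0)
        assert res.value == pytest.approx(expected)
        assert not res.out_of_range

    def test_out_of_range_flagged_not_clipped(self):
        res = percent_surface_expression(600.0, 500.0, 20.0)
        assert res.value > 100 and res.out_of_range

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValidationError):
            percent_surface_expression(10.0, 5.0, 5.0)
        with pytest.raises(ValidationError):
            percent_inhibition(10.0, 7.0, 7.0)

    @pytest.mark.parametrize(
        "signal,expected", [(900.0, 0.0), (100.0, 100.0), (500.0, 50.0)]
    )
    def test_inhibition_anchors(self, signal, expected):
        res = percent_inhibition(signal, signal_no_competitor=900.0, signal_full_competition=100.0)
        assert res.value == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(offset=st.floats(-1e4, 1e4))
    def test_affine_invariance(self, offset):
        """A constant offset on all raw signals (an unsubtracted
        background) cancels in both normalizations."""
        base = percent_surface_expression(260.0, 500.0, 20.0).value
        shifted = percent_surface_expression(260.0 + offset, 500.0 + offset, 20.0 + offset).value
        assert shifted == pytest.approx(base, abs=1e-6)
        base_i = percent_inhibition(500.0, 900.0, 100.0).value
        shifted_i = percent_inhibition(500.0 + offset, 900.0 + offset, 100.0 + offset).value
        assert shifted_i == pytest.approx(base_i, abs=1e-6)


class TestFourPLFit:
    def test_noise_free_recovery(self):
        true = FourPL(bottom=100.0, top=8000.0, ec50=0.04, hill=1.3)
        conc = np.array([10.0 / 10**i for i in range(6)][::-1])
        resp = true.response(conc)
        fit = fit_4pl(conc, resp, seed=0)
        assert fit.curve.ec50 == pytest.approx(true.ec50, rel=1e-3)
        assert fit.curve.hill == pytest.approx(true.hill, rel=1e-3)
        assert fit.curve.bottom == pytest.approx(true.bottom, rel=1e-3, abs=1.0)
        assert fit.curve.top == pytest.approx(true.top, rel=1e-3)

    def test_half_maximal_response_at_ec50(self):
        curve = FourPL(bottom=10.0, top=90.0, ec50=0.7, hill=2.3)
        assert curve.response(0.7) == pytest.approx(50.0)
        assert curve.inverse(50.0) == pytest.approx(0.7)

    def test_decreasing_curve_supported(self):
        """Surface-expression standard curves decrease with antibody
        concentration; the fit must handle top < bottom."""
        true = FourPL(bottom=100.0, top=5.0, ec50=0.1, hill=1.0)
        conc = np.geomspace(1e-3, 10, 8)
        fit = fit_4pl(conc, true.response(conc), seed=0)
        assert fit.curve.ec50 == pytest.approx(0.1, rel=1e-3)

    def test_median_ec50_error_under_noise(self):
        """8-point curves with 2% multiplicative noise, 50 seeds: the
        median |EC50 error| stays within 5%."""
        true = FourPL(bottom=50.0, top=5000.0, ec50=0.05, hill=1.1)
        conc = np.geomspace(1e-4, 10, 8)
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            resp = true.response(conc) * np.exp(0.02 * rng.standard_normal(len(conc)))
            fit = fit_4pl(conc, resp, seed=seed)
            errors.append(abs(fit.curve.ec50 - true.ec50) / true.ec50)
        assert np.median(errors) <= 0.05

    def test_unbracketed_curve_rejected(self):
        conc = np.geomspace(10, 1000, 6)   # all far above EC50: flat top
        true = FourPL(bottom=0.0, top=100.0, ec50=0.01, hill=1.0)
        with pytest.raises(CalibrationError, match="not bracketed"):
            fit_4pl(conc, true.response(conc), seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_4pl([0.1, 1.0, 10.0, 100.0], [1.0, 10.0, 50.0, 90.0], seed=0)


@pytest.fixture(scope="module")
def curve():
    true = FourPL(bottom=30.0, top=6000.0, ec50=0.06, hill=1.2)
    conc = np.array(sorted(10.0 / 10**i for i in range(6)))
    return StandardCurve.from_data(conc, true.response(conc), seed=1)


class TestPseudoConcentration:

    def test_round_trip_at_standard_levels(self, curve):
        for c in curve.concentrations[1:-1]:
            resp = curve.fourpl.response(c)
            out = pseudo_concentration(resp, curve)
            assert out.value == pytest.approx(c, rel=5e-3)

    def test_forward_inverse_at_patient_level(self, curve):
        resp = curve.fourpl.response(0.078)
        out = pseudo_concentration(resp, curve)
        assert out.value == pytest.approx(0.078, rel=0.01)

    def test_censoring_outside_quantifiable_range(self, curve):
        lo, hi = curve.quantifiable_response_range
        below = pseudo_concentration(lo - 1.0, curve)
        assert below.censored == "below" and below.value is None
        above = pseudo_concentration(hi + 1.0, curve)
        assert above.censored == "above" and above.value is None

    def test_unfitted_curve_rejected(self):
        raw = StandardCurve(
            concentrations=np.geomspace(1e-4, 10, 6),
            responses=np.linspace(1, 100, 6),
        )
        with pytest.raises(CalibrationError):
            pseudo_concentration(50.0, raw)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        log_ec50=st.floats(-3, 0),
        hill=st.floats(0.6, 2.5),
        top=st.floats(1000, 10000),
        frac=st.floats(0.05, 0.95),
    )
    def test_inverse_of_forward_is_identity(self, log_ec50, hill, top, frac):
        """pseudo_concentration after the forward curve recovers the
        concentration to 1% anywhere inside the quantifiable range."""
        curve4 = FourPL(bottom=20.0, top=top, ec50=10**log_ec50, hill=hill)
        conc = np.array(sorted(10.0 / 10**i for i in range(6)))
        sc = StandardCurve.from_data(conc, curve4.response(conc), seed=2)
        lo, hi = sc.quantifiable_concentration_range
        c_true = lo * (hi / lo) ** frac
        out = pseudo_concentration(sc.fourpl.response(c_true), sc)
        assert out.value == pytest.approx(c_true, rel=0.01)


class TestPatientPanel:
    def test_ratio_worked_examples(self):
        pair1 = ConcordancePair("#1", 2.2, 0.15)
        assert csf_serum_ratio(pair1) == 6.8
        pair4 = ConcordancePair("#4", 0.65, 0.078)
        assert csf_serum_ratio(pair4) == 12.0

    def test_full_panel_ratio_column(self):
        """All six complete patients reproduce the reported ratio column
        after one-decimal half-up rounding."""
        expected = {"#1": 6.8, "#3": 7.5, "#4": 12.0, "#5": 3.3, "#6": 2.7, "#7": 6.3}
        for pair in PATIENT_PANEL:
            if pair.complete:
                assert csf_serum_ratio(pair) == expected[pair.patient_id]
            else:
                assert csf_serum_ratio(pair) is None

    def test_half_up_rounding_on_exact_tie(self):
        # 0.015/0.24 = 6.25% exactly; half-up gives 6.3, banker's would not
        assert round_half_up(6.25, 1) == 6.3

    def test_zero_csf_is_zero_ratio(self):
        assert csf_serum_ratio(ConcordancePair("x", 1.0, 0.0)) == 0.0


class TestConcordance:
    def test_collinear_pairs_r2_one(self):
        pairs = [ConcordancePair(str(i), float(i), 0.1 * i + 0.05) for i in range(1, 6)]
        stats = concordance_stats(pairs)
        assert stats.r_squared == pytest.approx(1.0)
        assert stats.slope == pytest.approx(0.1)

    def test_patient_panel_concordance(self):
        """The six complete pairs give R² ~ 0.85 and p < 0.05 (reported
        0.847 / 0.0093 from unrounded inputs)."""
        stats = concordance_stats(PATIENT_PANEL)
        assert stats.n == 6
        assert stats.r_squared == pytest.approx(0.847, abs=0.02)
        assert stats.p_value < 0.05

    def test_p_value_equals_f_test(self):
        """Independent oracle: slope t-test p equals the regression
        F-test p (t² = F) from statsmodels."""
        import statsmodels.api as sm

        pairs = [p for p in PATIENT_PANEL if p.complete]
        stats = concordance_stats(pairs)
        x = np.array([p.serum_value for p in pairs])
        y = np.array([p.csf_value for p in pairs])
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert stats.p_value == pytest.approx(ols.f_pvalue, rel=1e-9)
        assert stats.r_squared == pytest.approx(ols.rsquared, rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            concordance_stats([ConcordancePair("a", 1.0, 0.1), ConcordancePair("b", 2.0, 0.2)])
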