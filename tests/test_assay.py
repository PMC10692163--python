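import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alscreen.assay import (
    AssayInputError,
    AtpaseMeasurement,
    calcein_efflux,
    fit_dose_response,
    fluorescence_slope,
    ic50_from_log,
    sensitive_atpase_activity,
    three_param_logistic,
)
from alscreen.synth_library import AssayTruth, generate_assay_fixtures


class TestFluorescenceSlope:
    def test_exact_line_recovers_slope_with_zero_se(self):
        t = np.arange(0, 100, 10.0)
        fit = fluorescence_slope(t, 5.0 + 2.0 * t, background=0.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_constant_signal_has_zero_slope(self):
        t = np.arange(5, dtype=float)
        assert fluorescence_slope(t, np.full(5, 33.0)).slope == pytest.approx(0.0)

    def test_background_subtraction(self):
        t = np.arange(10, dtype=float)
        with_bg = fluorescence_slope(t, 100.0 + 3.0 * t, background=100.0)
        assert with_bg.intercept == pytest.approx(0.0, abs=1e-9)
        assert with_bg.slope == pytest.approx(3.0)

    def test_noisy_recovery_within_three_se(self, rng):
        t = np.arange(30, dtype=float)
        signal = 10 + 100.0 * t + rng.normal(0, 5, size=30)
        fit = fluorescence_slope(t, signal)
        assert abs(fit.slope - 100.0) < 3 * fit.stderr

    def test_input_validation(self):
        with pytest.raises(AssayInputError, match="3 time points"):
            fluorescence_slope([0, 1], [1, 2])
        with pytest.raises(AssayInputError, match="increasing"):
            fluorescence_slope([0, 2, 1], [1, 2, 3])


class TestCalceinEfflux:
    def test_equal_slopes_give_unity(self):
        assert calcein_efflux(80.0, 80.0) == 1.0

    def test_doubled_slope_gives_half(self):
        assert calcein_efflux(2 * 60.0, 60.0) == pytest.approx(0.5)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identity_for_any_nonzero_slope(self, m):
        assert calcein_efflux(m, m) == pytest.approx(1.0)

    def test_zero_and_near_zero_compound_slope(self):
        with pytest.raises(AssayInputError, match="zero"):
            calcein_efflux(0.0, 100.0)
        with pytest.warns(UserWarning, match="near zero"):
            calcein_efflux(1e-9, 100.0)
        with pytest.raises(AssayInputError, match="control"):
            calcein_efflux(10.0, 0.0)


class TestDoseResponseFit:
    CONC = np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0])

    def test_noiseless_exact_recovery(self):
        y = three_param_logistic(np.log10(self.CONC), 1.0, 0.0, 0.5)
        fit = fit_dose_response(self.CONC, y)
        assert fit.top == pytest.approx(1.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.log_ic50 == pytest.approx(0.5, abs=1e-6)
        assert fit.se_log_ic50 == pytest.approx(0.0, abs=1e-6)
        assert fit.ic50 == pytest.approx(10**0.5, rel=1e-6)

    def test_midpoint_self_consistency(self):
        y = three_param_logistic(np.log10(self.CONC), 2.0, 0.4, 0.8)
        fit = fit_dose_response(self.CONC, y)
        mid = three_param_logistic(fit.log_ic50, fit.top, fit.bottom, fit.log_ic50)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2)

    def test_noisy_calibration_bias_and_coverage(self):
        """100 seeded noisy curves: mean LogIC50 within 0.02 of truth and
        ≥90% of ±1.96·SE intervals cover it."""
        rng = np.random.default_rng(77)
        conc = np.tile(self.CONC, 3)
        truth = 0.5
        estimates, covered = [], 0
        for _ in range(100):
            y = three_param_logistic(np.log10(conc), 1.0, 0.0, truth)
            y = y + rng.normal(0, 0.05, size=y.shape)
            fit = fit_dose_response(conc, y)
            estimates.append(fit.log_ic50)
            if abs(fit.log_ic50 - truth) <= 1.96 * fit.se_log_ic50:
                covered += 1
        assert abs(np.mean(estimates) - truth) < 0.02
        assert covered >= 90

    def test_stimulation_shaped_data_fits_with_top_below_bottom(self):
        y = three_param_logistic(np.log10(self.CONC), 0.2, 1.5, 0.0)  # increasing
        fit = fit_dose_response(self.CONC, y)
        assert fit.top < fit.bottom
        assert fit.log_ic50 == pytest.approx(0.0, abs=1e-6)

    def test_unit_rescaling_shifts_log_ic50(self):
        y = three_param_logistic(np.log10(self.CONC), 1.0, 0.0, 0.5)
        nanomolar = fit_dose_response(self.CONC * 1000, y)  # µM→nM relabel
        assert nanomolar.log_ic50 == pytest.approx(0.5 + 3.0, abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(AssayInputError, match="positive"):
            fit_dose_response([0.0, 1, 10, 100], [1, 1, 0, 0])
        with pytest.raises(AssayInputError, match="4 distinct"):
            fit_dose_response([1, 1, 10, 10], [1, 1, 0, 0])

    def test_fixture_chain_recovery(self):
        truth = AssayTruth(top=1.0, bottom=0.1, log_ic50=0.9)
        tables = generate_assay_fixtures(truth, noise_sd=0.02, seed=5)
        df = tables["dose_response"]
        fit = fit_dose_response(df["concentration_uM"], df["response"])
        assert fit.log_ic50 == pytest.approx(0.9, abs=0.1)
        assert fit.top == pytest.approx(1.0, abs=0.05)


class TestIc50FromLog:
    @pytest.mark.parametrize(
        "log_value, printed, digits",
        [(-0.96, 0.11, 2), (2.51, 324, 0), (0.0, 1.0, 2)],
    )
    def test_matches_reported_pairings(self, log_value, printed, digits):
        assert round(ic50_from_log(log_value), digits or None) == pytest.approx(printed)

    @given(st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverse_of_log10(self, ic50):
        assert ic50_from_log(np.log10(ic50)) == pytest.approx(ic50, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(AssayInputError):
            ic50_from_log(float("nan"))


def _measurement(absorbance, vanadate, std_abs=(0.0, 0.1, 0.5, 1.0), std_nmol=(0.0, 0.1, 0.5, 1.0),
                 time_min=60.0, protein_mg=0.05):
    return AtpaseMeasurement(
        absorbance=absorbance,
        time_min=time_min,
        protein_mg=protein_mg,
        vanadate=vanadate,
        standards_absorbance=std_abs,
        standards_nmol=std_nmol,
    )


class TestAtpaseActivity:
    def test_hand_arithmetic_through_identity_curve(self):
        # standard curve through origin with slope 1 absorbance per nmol
        test = _measurement(0.5, vanadate=False)
        ref = _measurement(0.1, vanadate=True)
        activity = sensitive_atpase_activity(test, ref)
        assert activity == pytest.approx((0.5 - 0.1) / (60.0 * 0.05))

    def test_equal_phosphate_with_and_without_vanadate_gives_zero(self):
        test = _measurement(0.4, vanadate=False)
        ref = _measurement(0.4, vanadate=True)
        assert sensitive_atpase_activity(test, ref) == pytest.approx(0.0)

    def test_negative_activity_reported_with_warning(self):
        test = _measurement(0.1, vanadate=False)
        ref = _measurement(0.4, vanadate=True)
        with pytest.warns(UserWarning, match="negative"):
            assert sensitive_atpase_activity(test, ref) < 0

    def test_fixture_tables_recover_known_activity(self):
        truth = AssayTruth()
        tables = generate_assay_fixtures(truth, noise_sd=0.0, seed=2)
        std = tables["atpase"], tables["atpase_standards"]
        atpase, standards = std
        row = atpase[(atpase.condition == "verapamil") & ~atpase.vanadate].iloc[0]
        ref = atpase[(atpase.condition == "verapamil") & atpase.vanadate].iloc[0]
        mk = lambda r, v: AtpaseMeasurement(
            r.absorbance, r.time_min, r.protein_mg, v,
            tuple(standards.absorbance), tuple(standards.nmol),
        )
        activity = sensitive_atpase_activity(mk(row, False), mk(ref, True))
        expected = (24.0 - 4.0) / (truth.reaction_time_min * truth.protein_mg)
        assert activity == pytest.approx(expected, rel=1e-9)

    def test_validation(self):
        with pytest.raises(AssayInputError, match="vanadate"):
            sensitive_atpase_activity(_measurement(0.5, False), _measurement(0.1, False))
        with pytest.raises(AssayInputError, match="share a standard curve"):
            sensitive_atpase_activity(
                _measurement(0.5, False), _measurement(0.1, True, std_abs=(0.0, 0.2, 0.6, 1.1))
            )
        flat = _measurement(0.5, False, std_abs=(1.0, 0.8, 0.5, 0.1))
        with pytest.raises(AssayInputError, match="slope"):
            sensitive_atpase_activity(flat, _measurement(0.1, True, std_abs=(1.0, 0.8, 0.5, 0.1)))
        with pytest.raises(AssayInputError):
            _measurement(0.5, False, time_min=0.0)
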