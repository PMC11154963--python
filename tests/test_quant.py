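"""Calibration, internal-standard selection, (semi)quantification."""

import numpy as np
import pytest

from wwscreen.pipeline import (
    PipelineParams,
    _ilis_sample_intensities,
    _sensitivity_factors,
)
from wwscreen.quant import (
    LinearSurrogatePredictor,
    fit_calibration,
    quantify_target,
    select_ilis,
    semiquant_negative,
    semiquant_positive,
    sensitivity_factor,
)


class TestFitCalibration:
    @pytest.mark.parametrize("weighting", ["1/X", "none"])
    def test_noiseless_line(self, weighting):
        levels = [(x, 2.0 * x) for x in (10, 50, 100, 500)]
        curve = fit_calibration(levels, weighting)
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)

    def test_two_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(10, 20), (100, 200)])

    def test_zero_concentration_rejected_under_1_over_x(self):
        with pytest.raises(ValueError):
            fit_calibration([(0, 1), (10, 20), (100, 200)], "1/X")

    def test_weighting_improves_low_end_accuracy(self):
        """Heteroscedastic (proportional) noise: the 1/X fit back-calculates
        the lowest level more accurately than the unweighted fit."""
        rng = np.random.default_rng(40)
        concs = np.array([1.0, 5.0, 10.0, 100.0, 500.0, 1000.0])
        errors = {"1/X": [], "none": []}
        for _ in range(200):
            responses = 3.0 * concs * np.exp(rng.normal(0, 0.08, concs.size))
            levels = list(zip(concs, responses))
            for weighting in errors:
                curve = fit_calibration(levels, weighting)
                back = curve.invert(3.0 * concs[0])
                errors[weighting].append(abs(back - concs[0]) / concs[0])
        assert np.mean(errors["1/X"]) < np.mean(errors["none"])

    def test_loq_is_lowest_accurate_level(self):
        levels = [(x, 2.0 * x) for x in (1, 10, 100)]
        assert fit_calibration(levels).loq == 1.0


class TestSelectIlis:
    CANDIDATES = [
        {"ilis_id": "A", "rt": 10.0, "relative_recovery": 80.0},
        {"ilis_id": "B", "rt": 11.0, "relative_recovery": 98.0},
        {"ilis_id": "C", "rt": 12.0, "relative_recovery": 120.0},
    ]

    def test_identical_ilis_wins_regardless_of_recovery(self):
        cands = self.CANDIDATES + [
            {"ilis_id": "D", "rt": 14.0, "relative_recovery": 60.0,
             "identical_to": "drug"}
        ]
        assert select_ilis("drug", 10.0, cands).ilis_id == "D"

    def test_recovery_closest_to_100_chosen(self):
        assert select_ilis("drug", 11.0, self.CANDIDATES).ilis_id == "B"

    def test_tie_broken_by_rt_distance(self):
        cands = [
            {"ilis_id": "A", "rt": 14.0, "relative_recovery": 95.0},
            {"ilis_id": "B", "rt": 11.0, "relative_recovery": 105.0},
        ]
        assert select_ilis("drug", 10.0, cands).ilis_id == "B"

    def test_empty_window_instructs_widening(self):
        with pytest.raises(ValueError, match="widen"):
            select_ilis("drug", 30.0, self.CANDIDATES, rt_window=1.0)


class TestQuantifyTarget:
    def _curve(self):
        return fit_calibration([(x, 0.002 * x) for x in (10, 100, 1000)])

    def test_inversion_recovers_level(self):
        curve = self._curve()
        out = quantify_target({"S1": 0.2}, {"S1": 1.0}, curve)
        assert out["S1"][0] == pytest.approx(100.0, rel=1e-9)

    def test_recovery_correction_doubles(self):
        curve = self._curve()
        full = quantify_target({"S1": 0.2}, {"S1": 1.0}, curve, 100.0)
        half = quantify_target({"S1": 0.2}, {"S1": 1.0}, curve, 50.0)
        assert half["S1"][0] == pytest.approx(2 * full["S1"][0])

    def test_round_trip_identity_on_range(self):
        curve = self._curve()
        for conc in (10.0, 55.0, 400.0, 1000.0):
            response = curve.slope * conc + curve.intercept
            back = quantify_target({"S": response}, {"S": 1.0}, curve)["S"][0]
            assert back == pytest.approx(conc, rel=1e-9)

    def test_nonpositive_ilis_rejected(self):
        with pytest.raises(ValueError):
            quantify_target({"S1": 0.2}, {"S1": 0.0}, self._curve())

    def test_planted_recovery_unbiased_after_correction(self):
        """A 50%-recovery analyte is biased 2x low uncorrected and unbiased
        after relative-recovery correction."""
        rng = np.random.default_rng(41)
        true_conc, recovery = 200.0, 50.0
        curve = self._curve()
        response = curve.slope * true_conc * (recovery / 100.0)
        raw = quantify_target({"S": response}, {"S": 1.0}, curve, 100.0)["S"][0]
        corrected = quantify_target({"S": response}, {"S": 1.0}, curve, recovery)["S"][0]
        assert raw == pytest.approx(true_conc / 2, rel=1e-9)
        assert corrected == pytest.approx(true_conc, rel=1e-9)

    def test_recovery_within_two_percent_at_five_percent_noise(self):
        rng = np.random.default_rng(42)
        curve = self._curve()
        true_conc = 300.0
        estimates = []
        for _ in range(500):
            response = curve.slope * true_conc * float(np.exp(rng.normal(0, 0.05)))
            estimates.append(
                quantify_target({"S": response}, {"S": 1.0}, curve)["S"][0]
            )
        assert np.mean(estimates) == pytest.approx(true_conc, rel=0.02)


class TestSensitivityFactor:
    def test_arithmetic(self):
        assert sensitivity_factor([5e5], [1e6]) == pytest.approx(2.0)

    def test_identity(self):
        assert sensitivity_factor([1e6, 1e6], [1e6, 1e6]) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_factor([], [1e6])

    def test_planted_suppression_recovered(self, demo_dataset):
        """The plant with a planted 0.5 suppression factor yields a
        sensitivity factor of 2."""
        factors = _sensitivity_factors(
            demo_dataset,
            _ilis_sample_intensities(demo_dataset, PipelineParams()),
        )
        gt = demo_dataset.ground_truth
        assert factors[gt.suppression_plant] == pytest.approx(
            1.0 / gt.suppression_factor, rel=0.05
        )
        others = [v for p, v in factors.items() if p != gt.suppression_plant]
        assert all(v == pytest.approx(1.0, rel=0.05) for v in others)


class TestSemiquant:
    def _external(self):
        return fit_calibration([(x, 100.0 * x) for x in (10, 100, 1000)])

    def test_on_curve_exact(self):
        curve = self._external()
        assert semiquant_negative(100.0 * 50.0, curve, 1.0) == pytest.approx(50.0)

    def test_factor_scales_effective_intensity(self):
        curve = self._external()
        assert semiquant_negative(5000.0, curve, 2.0) == pytest.approx(
            curve.invert(10000.0)
        )

    def test_suppressed_analyte_corrected(self):
        """With 0.5 suppression, the corrected estimate is unbiased; the
        uncorrected one is biased low."""
        curve = self._external()
        true_conc, suppression = 200.0, 0.5
        measured = 100.0 * true_conc * suppression
        uncorrected = semiquant_negative(measured, curve, 1.0)
        corrected = semiquant_negative(measured, curve, 1.0 / suppression)
        assert corrected == pytest.approx(true_conc, rel=0.2)
        assert uncorrected < 0.75 * true_conc

    def test_positive_mode_oracle_predictor_exact(self):
        predictor = LinearSurrogatePredictor({"met": 250.0})
        out = semiquant_positive("met", {"S1": 250.0 * 80.0}, predictor)
        assert out["S1"] == pytest.approx(80.0)

    def test_positive_mode_bias_propagates_transparently(self):
        truth = LinearSurrogatePredictor({"met": 250.0})
        biased = LinearSurrogatePredictor({"met": 250.0}, bias=2.0)
        exact = semiquant_positive("met", {"S1": 1e4}, truth)["S1"]
        off = semiquant_positive("met", {"S1": 1e4}, biased)["S1"]
        assert off == pytest.approx(exact / 2.0)

    def test_calibrant_anchoring_rescales(self):
        predictor = LinearSurrogatePredictor({"met": 1.0, "cal": 1.0})
        # measured calibrant response factor is 500 counts per ng/L
        out = semiquant_positive(
            "met", {"S1": 500.0 * 120.0}, predictor,
            calibrants=[("cal", 10.0, 5000.0)],
        )
        assert out["S1"] == pytest.approx(120.0)

    def test_missing_predictor_reports_unquantified(self):
        assert semiquant_positive("met", {"S1": 1.0}, None) is None
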