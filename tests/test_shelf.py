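"""Shelf-life determination under safety, sensory and quality limits."""

import numpy as np
import pytest

from freshshelf import (
    AcceptabilityLimit,
    GrowthCurveModel,
    QualityKineticsModel,
    ShelfLifeEstimate,
    StorageDataset,
    derive_attribute_cutoff,
    evaluate_gompertz,
    invert_growth,
    invert_quality,
    overall_shelf_life,
    predict_quality_shelf_life,
    predict_safety_shelf_life,
    QualityParams,
    sensory_shelf_life,
    shelf_life_report,
)

DAYS = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
SCORES = [5.0, 4.5, 4.0, 3.2, 2.8, 2.5]


class TestSensory:
    def test_discrete_convention(self):
        est = sensory_shelf_life(list(zip(DAYS, SCORES)))
        assert est.t_pred == 6.0
        assert est.basis == "sensory" and not est.censored

    def test_interpolation_convention(self):
        est = sensory_shelf_life(list(zip(DAYS, SCORES)), method="interpolate")
        assert est.t_pred == pytest.approx(7.0)

    def test_all_above_limit_right_censored(self):
        est = sensory_shelf_life(list(zip(DAYS, [5, 5, 4.8, 4.5, 4.2, 4.0])))
        assert est.t_pred == 10.0 and est.censored

    def test_all_below_limit(self):
        est = sensory_shelf_life(list(zip(DAYS, [2.9, 2.5, 2, 2, 1.5, 1])))
        assert est.t_pred == 0.0 and est.status == "exceeded_at_start"


def _mini_dataset(values_by_day, attribute="ascorbic_mg_kg", treatment="CK"):
    records = [
        (treatment, d, attribute, 1, v) for d, v in zip(DAYS, values_by_day)
    ]
    return StorageDataset.from_records(records)


class TestCutoffDerivation:
    def test_exponential_trajectory_day8(self):
        vals = 236.9 * np.exp(-0.049 * DAYS)
        cut = derive_attribute_cutoff(_mini_dataset(vals), "ascorbic_mg_kg", "CK", 8.0)
        assert cut.value == pytest.approx(160.0743, abs=1e-3)
        assert cut.direction == "lower"

    def test_interpolates_between_sampled_days(self):
        vals = 10.0 - DAYS  # linear decline
        cut = derive_attribute_cutoff(_mini_dataset(vals), "ascorbic_mg_kg", "CK", 5.0)
        assert cut.value == pytest.approx(5.0)

    def test_rising_attribute_upper_direction(self):
        cut = derive_attribute_cutoff(
            _mini_dataset(0.41 * DAYS, "weight_loss_pct"), "weight_loss_pct", "CK", 6.0
        )
        assert cut.direction == "upper"

    def test_outside_range_raises(self):
        with pytest.raises(ValueError):
            derive_attribute_cutoff(_mini_dataset(10 - DAYS), "ascorbic_mg_kg", "CK", 12.0)


class TestSafety:
    def test_matches_closed_form_inversion(self, gompertz_ck):
        counts = evaluate_gompertz(DAYS, gompertz_ck)
        fit = GrowthCurveModel(DAYS, counts, "gompertz").fit()
        est = predict_safety_shelf_life(fit, 5.0)
        assert est.t_pred == pytest.approx(0.695081159203325, abs=1e-3)
        assert est.basis == "safety" and est.model == "gompertz"

    def test_never_reached_and_exceeded_signals(self, gompertz_ck):
        counts = evaluate_gompertz(DAYS, gompertz_ck)
        fit = GrowthCurveModel(DAYS, counts, "gompertz").fit()
        high = predict_safety_shelf_life(fit, gompertz_ck.nmax + 1.0)
        assert high.status == "never_reached" and high.censored
        low = predict_safety_shelf_life(fit, 4.0)
        assert low.status == "exceeded_at_start" and low.t_pred == 0.0

    def test_monotone_in_limit(self, gompertz_pdt):
        limits = np.linspace(3.0, 7.5, 12)
        times = [invert_growth("gompertz", gompertz_pdt, l) for l in limits]
        assert np.all(np.diff(times) > 0)


class TestQuality:
    def test_first_order_ascorbic(self):
        vals = 236.9 * np.exp(-0.049 * DAYS)
        fit = QualityKineticsModel(DAYS, vals, "first").fit()
        cut = AcceptabilityLimit("ascorbic_mg_kg", 162.50, "lower")
        est = predict_quality_shelf_life(fit, cut)
        assert est.t_pred == pytest.approx(7.693, abs=1e-3)
        assert est.model == "first-order"

    def test_zero_order_weight_loss(self):
        vals = 0.415 * DAYS
        fit = QualityKineticsModel(DAYS, vals, "zero").fit()
        est = predict_quality_shelf_life(
            fit, AcceptabilityLimit("weight_loss_pct", 2.0, "upper")
        )
        assert est.t_pred == pytest.approx(4.819, abs=1e-3)

    def test_cutoff_equal_a0_is_immediate(self):
        fit = QualityKineticsModel(DAYS, 100.0 * np.exp(-0.05 * DAYS), "first").fit()
        est = predict_quality_shelf_life(
            fit, AcceptabilityLimit("ascorbic_mg_kg", 100.0, "lower")
        )
        assert est.t_pred == 0.0 and est.status == "exceeded_at_start"

    def test_decreasing_in_cutoff_for_declining_attribute(self):
        q = QualityParams("first", 200.0, -0.05)
        cutoffs = np.linspace(50.0, 190.0, 10)
        times = [invert_quality(q, c) for c in cutoffs]
        assert np.all(np.diff(times) < 0)


class TestReport:
    @staticmethod
    def _est(basis, t, trt="CK", attribute="x", censored=False):
        return ShelfLifeEstimate(
            basis, t, AcceptabilityLimit(attribute, 1.0, "upper"), "m", trt,
            censored=censored,
        )

    def test_minimum_rule(self):
        df = shelf_life_report([self._est("safety", 1.5), self._est("quality", 5.9)])
        assert overall_shelf_life(df)["CK"] == pytest.approx(1.5)

    def test_only_sensory(self):
        df = shelf_life_report([self._est("sensory", 6.0)])
        assert overall_shelf_life(df)["CK"] == pytest.approx(6.0)

    def test_overall_not_above_any_basis(self):
        ests = [self._est("safety", 2.0), self._est("sensory", 6.0),
                self._est("quality", 4.0)]
        df = shelf_life_report(ests)
        overall = overall_shelf_life(df)["CK"]
        assert all(overall <= e.t_pred for e in ests)

    def test_mimic_pdt_outlasts_control(self, sigma0_dataset):
        from freshshelf import analyze_trial

        analysis = analyze_trial(sigma0_dataset)
        overall = overall_shelf_life(analysis.report)
        assert overall["PDT"] >= overall["CK"]

    def test_text_rendering_aligned(self):
        from freshshelf import format_report_text

        df = shelf_life_report([self._est("safety", 1.5)])
        text = format_report_text(df)
        lines = text.splitlines()
        assert len({len(l) for l in lines if l.strip()}) <= 2
        assert "t_pred_d" in lines[0]
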