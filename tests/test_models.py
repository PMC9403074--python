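"""Deterministic chart arithmetic: distensibility, polynomials, z-scores, percentiles."""

import json
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aortaref as ar
from aortaref import errors
from aortaref.models import PolyModel, ReferenceChart


class TestDistensibility:
    @pytest.mark.parametrize(
        "dmax,dmin,expected",
        [
            (4.2, 4.2, 0.0),
            (4.62, 4.2, 0.10),
            (3.80, 2.80, (3.80 - 2.80) / 2.80),
        ],
    )
    def test_values(self, dmax, dmin, expected):
        assert ar.distensibility(dmax, dmin) == pytest.approx(expected, abs=1e-12)

    def test_percent_presentation(self):
        assert ar.distensibility_percent(4.62, 4.2) == pytest.approx(10.0)

    def test_nonpositive_dmin_rejected(self):
        with pytest.raises(errors.InvalidMeasurementError):
            ar.distensibility(4.0, 0.0)

    def test_inconsistent_frames_rejected(self):
        with pytest.raises(errors.InconsistentFramesError):
            ar.distensibility(2.0, 3.0)

    @given(
        d=st.floats(min_value=0.1, max_value=100.0),
        f=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_expansion_identity(self, d, f):
        # distensibility of a vessel expanding by fraction f is exactly f
        assert ar.distensibility(d * (1 + f), d) == pytest.approx(f, abs=1e-9)


class TestPolyEvaluation:
    def test_dmax_ga_mean_at_24_weeks(self, dmax_ga_chart):
        assert dmax_ga_chart.predict_mean(24) == pytest.approx(3.45736, abs=1e-9)

    def test_dmax_ga_mean_at_term(self, dmax_ga_chart):
        assert dmax_ga_chart.predict_mean(40) == pytest.approx(6.386, abs=1e-9)

    def test_intercept_only_at_zero_predictor(self, sanitized_registry):
        model = sanitized_registry[("DD", "BPD")].mean_model
        assert ar.evaluate_poly(model, 0.0) == pytest.approx(0.8)

    def test_empty_term_list_rejected(self):
        with pytest.raises(errors.MalformedModelError):
            PolyModel(predictor="GA", terms=())

    def test_duplicate_powers_rejected(self):
        with pytest.raises(errors.MalformedModelError):
            PolyModel(predictor="GA", terms=((1, 2.0), (1, 3.0)))

    def test_out_of_range_warns_not_errors(self, dmax_ga_chart):
        with pytest.warns(errors.ExtrapolationWarning):
            value = dmax_ga_chart.predict_mean(16.0)
        assert np.isfinite(value)

    def test_nonfinite_predictor_rejected(self, dmax_ga_chart):
        with pytest.raises(ValueError):
            ar.evaluate_poly(dmax_ga_chart.mean_model, float("nan"))


class TestPredictSD:
    def test_dmax_ga_sd_at_24_weeks(self, dmax_ga_chart):
        assert dmax_ga_chart.predict_sd(24) == pytest.approx(0.397, abs=1e-9)

    def test_sd_root_raises_domain_error(self, dmax_ga_chart):
        # the linear SD model crosses zero at GA = 0.227/0.026 weeks
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", errors.ExtrapolationWarning)
            with pytest.raises(errors.ChartDomainError):
                dmax_ga_chart.predict_sd(0.227 / 0.026)

    def test_dd_ga_sd_as_printed(self, printed_registry):
        # printed slope −0.255e−3/week gives 0.13388 at 24 weeks
        chart = printed_registry[("DD", "GA")]
        assert chart.predict_sd(24) == pytest.approx(0.13388, abs=1e-9)


class TestZScore:
    def test_worked_example(self):
        res = ar.zscore(0.105, 0.344, 0.0816)
        assert res.z == pytest.approx(-2.93, abs=5e-3)
        assert res.band_flag == "outside_90"

    def test_observation_at_mean(self):
        res = ar.zscore(3.2, 3.2, 0.5)
        assert res.z == 0.0
        assert res.band_flag == "within_90"

    def test_one_sd_above_mean(self):
        res = ar.zscore(3.854, 3.457, 0.397)
        assert res.z == pytest.approx(1.0, abs=1e-12)
        assert res.band_flag == "within_90"

    def test_threshold_is_strict(self):
        assert ar.zscore(1.65, 0.0, 1.0).band_flag == "within_90"
        assert ar.zscore(1.6500001, 0.0, 1.0).band_flag == "outside_90"

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(errors.InvalidSDError):
            ar.zscore(1.0, 0.0, 0.0)


class TestScoreRecord:
    def test_worked_example_via_chart(self):
        # a chart carrying the published worked-example mean/SD at 24 weeks
        chart = ReferenceChart(
            response="DD",
            mean_model=PolyModel("GA", ((0, 0.344),), "published_sanitized"),
            sd_model=PolyModel("GA", ((0, 0.0816),), "published_sanitized"),
            predictor_range=(18.0, 40.0),
        )
        rec = ar.BiometryRecord(ga=24, dmax=1.105 * 2.8, dmin=2.8)  # dd = 0.105
        res = ar.score_record(rec, "DD", "GA", {("DD", "GA"): chart})
        assert res.z == pytest.approx(-2.93, abs=5e-3)
        assert res.outside_band

    def test_zero_z_at_published_mean(self, sanitized_registry):
        mean = sanitized_registry[("Dmax", "GA")].predict_mean(24)
        rec = ar.BiometryRecord(ga=24, dmax=mean, dmin=mean / 1.3)
        res = ar.score_record(rec, "Dmax", "GA", sanitized_registry)
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_unknown_chart_rejected(self, sanitized_registry):
        rec = ar.BiometryRecord(ga=24, dmax=3.5, dmin=2.7)
        with pytest.raises(errors.UnknownChartError):
            ar.score_record(rec, "Dmax", "GA", {})

    def test_missing_predictor_rejected(self, sanitized_registry):
        rec = ar.BiometryRecord(ga=24, dmax=3.5, dmin=2.7, bpd=None)
        with pytest.raises(errors.IncompleteRecordError):
            ar.score_record(rec, "Dmax", "BPD", sanitized_registry)

    def test_scale_invariance_fraction_vs_percent(self):
        # scoring dd as a fraction equals scoring dd×100 against the ×100 chart
        frac = ReferenceChart(
            response="DD",
            mean_model=PolyModel("GA", ((0, 0.45), (1, -0.005)), "published_sanitized"),
            sd_model=PolyModel("GA", ((0, 0.09),), "published_sanitized"),
            predictor_range=(18.0, 40.0),
        )
        pct = ReferenceChart(
            response="DD",
            mean_model=PolyModel("GA", ((0, 45.0), (1, -0.5)), "published_sanitized"),
            sd_model=PolyModel("GA", ((0, 9.0),), "published_sanitized"),
            predictor_range=(18.0, 40.0),
        )
        z_frac = frac.score(0.105, 24.0).z
        z_pct = pct.score(10.5, 24.0).z
        assert z_frac == pytest.approx(z_pct, rel=1e-12)


class TestPercentileCurves:
    def test_median_equals_mean_model(self, dmax_ga_chart):
        grid = np.linspace(18, 40, 23)
        (curve,) = ar.percentile_curves(dmax_ga_chart, grid, [50])
        np.testing.assert_allclose(curve.values, dmax_ga_chart.mean_model(grid))

    def test_p95_at_24_weeks(self, dmax_ga_chart):
        (curve,) = ar.percentile_curves(dmax_ga_chart, [24.0], [95])
        # mean 3.45736 + Phi^{-1}(0.95)·0.397; the exact quantile is 1.64485
        assert curve.values[0] == pytest.approx(3.45736 + 1.6449 * 0.397, abs=2e-4)

    def test_p5_symmetric_about_median(self, dmax_ga_chart):
        grid = np.linspace(18, 40, 12)
        p5, p50, p95 = ar.percentile_curves(dmax_ga_chart, grid, [5, 50, 95])
        mid = (np.array(p5.values) + np.array(p95.values)) / 2
        np.testing.assert_allclose(mid, p50.values, rtol=1e-12)

    def test_p5_at_24_weeks(self, dmax_ga_chart):
        (p5,) = ar.percentile_curves(dmax_ga_chart, [24.0], [5])
        assert p5.values[0] == pytest.approx(2.8043, abs=2e-4)

    def test_empty_grid_rejected(self, dmax_ga_chart):
        with pytest.raises(errors.EmptyInputError):
            ar.percentile_curves(dmax_ga_chart, [], [50])


class TestChartSerialization:
    def test_json_round_trip_is_exact(self, sanitized_registry, tmp_path):
        for chart in sanitized_registry.values():
            path = tmp_path / "chart.json"
            chart.to_json(path)
            loaded = ReferenceChart.from_json(path)
            assert loaded.mean_model.terms == chart.mean_model.terms
            assert loaded.sd_model.terms == chart.sd_model.terms
            assert loaded.predictor_range == chart.predictor_range
            assert loaded.response == chart.response

    def test_json_fields(self, dmax_ga_chart):
        d = json.loads(dmax_ga_chart.to_json())
        assert set(d) >= {"response", "predictor", "terms", "sd_terms", "range", "provenance"}
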