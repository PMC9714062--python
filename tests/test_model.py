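"""Unit and property tests for the vault predictor and selection rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iclvault import (
    DEFAULT_COEFFICIENTS,
    ICL_SIZES,
    BiometryRecord,
    ModelCoefficients,
    TargetWindow,
    ValidationRecord,
    assign_error_group,
    classify_vault,
    predict_vault,
    select_icl_size,
    vault_step,
)
from conftest import record_with_prediction

biometry_st = st.builds(
    BiometryRecord,
    sts_horizontal=st.floats(9.5, 14.0),
    sts_vertical=st.floats(9.5, 14.0),
    lens_thickness=st.floats(2.8, 5.0),
)


class TestPredictVault:
    def test_population_mean_eye(self, population_mean_record):
        # hand evaluation of the linear formula at the population means
        assert predict_vault(population_mean_record, 12.6) == pytest.approx(364.26, abs=0.01)

    def test_thicker_lens_lowers_vault_by_its_coefficient(self, population_mean_record):
        thicker = BiometryRecord(11.54, 11.96, 3.67 + 1.0)
        delta = predict_vault(thicker, 12.6) - predict_vault(population_mean_record, 12.6)
        assert delta == pytest.approx(-432.497, abs=1e-9)

    @given(r1=biometry_st, r2=biometry_st, size=st.sampled_from(ICL_SIZES))
    @settings(max_examples=200, deadline=None)
    def test_linearity_in_covariates(self, r1, r2, size):
        """Prediction differences equal the coefficient dot the coordinate
        differences — the formula is affine with no hidden state."""
        c = DEFAULT_COEFFICIENTS
        expected = (
            c.coef_sts_h * (r1.sts_horizontal - r2.sts_horizontal)
            + c.coef_lt * (r1.lens_thickness - r2.lens_thickness)
            + c.coef_sts_v * (r1.sts_vertical - r2.sts_vertical)
        )
        got = predict_vault(r1, size) - predict_vault(r2, size)
        assert got == pytest.approx(expected, abs=1e-9)

    @given(record=biometry_st)
    @settings(max_examples=200, deadline=None)
    def test_predictions_strictly_increase_with_size(self, record):
        preds = [predict_vault(record, s) for s in ICL_SIZES]
        assert all(a < b for a, b in zip(preds, preds[1:]))

    def test_invalid_size_rejected(self, population_mean_record):
        with pytest.raises(ValueError, match="ICL size"):
            predict_vault(population_mean_record, 12.3)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("sts_horizontal", 7.9),
            ("sts_horizontal", 16.1),
            ("sts_vertical", 5.0),
            ("lens_thickness", 2.4),
            ("lens_thickness", 6.5),
        ],
    )
    def test_out_of_range_biometry_names_the_field(self, field, value):
        kwargs = {"sts_horizontal": 11.5, "sts_vertical": 11.9, "lens_thickness": 3.7}
        kwargs[field] = value
        with pytest.raises(ValueError, match=field):
            BiometryRecord(**kwargs)

    def test_unknown_ubm_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown UBM"):
            BiometryRecord(11.5, 11.9, 3.7, ubm_features=frozenset({"sulcus_spur"}))


class TestVaultStep:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(12.1, 12.6, 329), (12.6, 13.2, 394), (13.2, 13.7, 329), (12.6, 12.6, 0)],
    )
    def test_printed_step_sizes(self, a, b, expected):
        assert vault_step(a, b) == expected

    @pytest.mark.parametrize("a", ICL_SIZES)
    @pytest.mark.parametrize("b", ICL_SIZES)
    def test_antisymmetry(self, a, b):
        assert vault_step(a, b) == -vault_step(b, a)

    def test_equal_first_and_last_steps(self):
        assert vault_step(12.1, 12.6) == vault_step(13.2, 13.7)


def oracle_select(record, window, adjust=False):
    """Brute-force reference: enumerate the four candidates directly."""
    preds = {s: predict_vault(record, s) for s in ICL_SIZES}
    feasible = sorted(s for s in ICL_SIZES if window.low <= preds[s] <= window.high)
    if not feasible:
        dist = lambda s: max(window.low - preds[s], preds[s] - window.high)
        best = min(ICL_SIZES, key=lambda s: (dist(s), s))
        return best, False, False
    best = min(feasible, key=lambda s: (abs(preds[s] - window.center), s))
    if adjust and "anterior_ciliary_body" in record.ubm_features and feasible[0] < best:
        return feasible[0], True, True
    return best, True, False


class TestSelectIclSize:
    @given(record=biometry_st, adjust=st.booleans())
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, record, adjust):
        res = select_icl_size(record, apply_feature_adjustment=adjust)
        sel, in_win, adj = oracle_select(record, TargetWindow(), adjust)
        assert (res.selected, res.in_window, res.adjusted_for_feature) == (sel, in_win, adj)

    @given(record=biometry_st)
    @settings(max_examples=200, deadline=None)
    def test_feasible_set_is_contiguous(self, record):
        """Monotone predictions make in-window sizes a contiguous run."""
        res = select_icl_size(record)
        w = TargetWindow()
        flags = [w.contains(res.predictions[s]) for s in ICL_SIZES]
        runs = sum(1 for a, b in zip([False] + flags, flags) if b and not a)
        assert runs <= 1

    def test_downsizing_example_680_to_351(self):
        """An eye predicting 680 μm at 12.6 mm downshifts to 12.1 mm with a
        predicted vault of 351 μm when the ciliary body is anteriorly
        positioned."""
        rec = record_with_prediction(680.0, size=12.6)
        rec = BiometryRecord(
            rec.sts_horizontal,
            rec.sts_vertical,
            rec.lens_thickness,
            ubm_features=frozenset({"anterior_ciliary_body"}),
        )
        res = select_icl_size(rec, apply_feature_adjustment=True)
        assert res.selected == 12.1
        assert res.in_window
        assert round(res.selected_prediction) == 351

    def test_single_feasible_size_selected(self):
        # predictions ~ {12.1: 150, 12.6: 479, 13.2: 873, 13.7: 1201}
        rec = record_with_prediction(150.0, size=12.1)
        res = select_icl_size(rec)
        assert res.predictions[12.6] == pytest.approx(478.56, abs=0.01)
        assert res.selected == 12.6
        assert res.in_window

    def test_all_predictions_below_window_selects_largest(self):
        rec = record_with_prediction(-900.0, size=12.1)
        assert all(p < 300 for p in select_icl_size(rec).predictions.values())
        res = select_icl_size(rec)
        assert res.selected == 13.7
        assert not res.in_window

    def test_negative_prediction_never_in_window(self):
        rec = record_with_prediction(-900.0, size=12.1)
        res = select_icl_size(rec)
        assert res.selected_prediction < 300
        assert not res.in_window


class TestClassification:
    @pytest.mark.parametrize(
        "vault,category",
        [
            (0.0, "low"),
            (199.9, "low"),
            (200.0, "normal"),
            (500.0, "normal"),
            (800.0, "normal"),
            (800.1, "high"),
            (1150.0, "high"),
        ],
    )
    def test_vault_categories(self, vault, category):
        assert classify_vault(vault) == category

    @given(vault=st.floats(0, 2000))
    @settings(max_examples=200, deadline=None)
    def test_exactly_one_category(self, vault):
        assert classify_vault(vault) in ("low", "normal", "high")
        assert classify_vault(vault) == classify_vault(vault)  # pure

    def test_negative_vault_rejected(self):
        with pytest.raises(ValueError):
            classify_vault(-1.0)

    @pytest.mark.parametrize(
        "error,group",
        [
            (-350.0, "overestimated"),
            (-300.0, "within"),
            (0.0, "within"),
            (300.0, "within"),
            (301.0, "underestimated"),
        ],
    )
    def test_error_groups_strict_threshold(self, error, group):
        assert assign_error_group(error) == group

    def test_non_finite_error_rejected(self):
        with pytest.raises(ValueError):
            assign_error_group(float("nan"))

    def test_validation_record_derives_consistent_fields(self):
        v = ValidationRecord(predicted_vault=500.0, actual_vault=850.0, stratum=2)
        assert v.category == "high"
        assert v.error == pytest.approx(350.0)
        assert v.error_group == "underestimated"


class TestConfiguration:
    def test_default_coefficients_are_the_published_values(self):
        assert DEFAULT_COEFFICIENTS.as_tuple() == (
            -1369.05,
            657.121,
            -287.408,
            -432.497,
            -137.33,
        )

    def test_coefficients_overridable(self, population_mean_record):
        c = ModelCoefficients(intercept=0, coef_size=100, coef_sts_h=0, coef_lt=0, coef_sts_v=0)
        assert predict_vault(population_mean_record, 12.6, c) == pytest.approx(1260.0)

    def test_window_requires_ordered_bounds(self):
        with pytest.raises(ValueError):
            TargetWindow(low=700, high=300, center=500)
        with pytest.raises(ValueError):
            TargetWindow(low=300, high=700, center=800)
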