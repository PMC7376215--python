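import numpy as np
import pytest
from scipy.special import expit

from oxrip.bench_assays import (
    convert_pg_per_ug_to_nm,
    convert_units,
    correct_cross_reactivity,
    dilution_concordance,
    dotblot_linearity,
    fit_standard_curve,
    interpolate_concentration,
    ip_efficiency,
    loading_normalize,
    truncation_index,
)


def _noiseless_curve(a=2.0, b=-0.8, concs=(15, 50, 150, 500, 1500)):
    concs = np.asarray(concs, dtype=float)
    bb0 = expit(a + b * np.log(concs))
    return fit_standard_curve(concs, bb0)


class TestStandardCurve:
    def test_noiseless_points_recover_parameters_exactly(self):
        curve = _noiseless_curve(a=2.0, b=-0.8)
        assert curve.a == pytest.approx(2.0, abs=1e-10)
        assert curve.b == pytest.approx(-0.8, abs=1e-10)

    def test_forward_inverse_identity(self):
        curve = _noiseless_curve()
        for conc in (12.0, 100.0, 900.0):
            assert curve.inverse(curve.forward(conc)) == pytest.approx(conc, rel=1e-9)

    def test_midpoint_closed_form(self):
        curve = _noiseless_curve(a=2.0, b=-0.8)
        assert curve.midpoint_conc == pytest.approx(np.exp(2.0 / 0.8), rel=1e-9)
        assert curve.forward(curve.midpoint_conc) == pytest.approx(0.5, abs=1e-9)
        assert curve.forward(curve.sensitivity_conc) == pytest.approx(0.8, abs=1e-9)
        assert curve.sensitivity_conc < curve.midpoint_conc

    def test_rising_curve_rejected(self):
        concs = np.array([15.0, 50.0, 150.0])
        bb0 = expit(-2.0 + 0.8 * np.log(concs))
        with pytest.raises(ValueError, match="competitive"):
            fit_standard_curve(concs, bb0)

    def test_saturated_points_excluded(self):
        concs = np.array([15.0, 50.0, 150.0, 500.0])
        bb0 = expit(2.0 - 0.8 * np.log(concs))
        bb0[0] = 1.1  # above maximum binding
        curve = fit_standard_curve(concs, bb0)
        assert curve.excluded_points == 1
        assert curve.n_points_used == 3


class TestInterpolation:
    def test_midpoint_reading_returns_midpoint_conc(self):
        curve = _noiseless_curve()
        conc, in_range = interpolate_concentration(curve, 0.5, 1.0)
        assert conc == pytest.approx(curve.midpoint_conc, rel=1e-9)
        assert in_range

    def test_dilution_scales_linearly(self):
        curve = _noiseless_curve()
        c1, _ = interpolate_concentration(curve, 0.4, 1.0)
        c2, _ = interpolate_concentration(curve, 0.4, 2.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_round_trip_through_forward_curve(self):
        curve = _noiseless_curve()
        for conc in (20.0, 120.0, 1000.0):
            reading = float(curve.forward(conc))
            back, _ = interpolate_concentration(curve, reading, 1.0)
            assert back == pytest.approx(conc, rel=1e-9)

    def test_out_of_linear_range_flagged(self):
        curve = _noiseless_curve()
        reading = float(curve.forward(5.0))  # below the 10.3 pg/ml floor
        _, in_range = interpolate_concentration(curve, reading, 1.0)
        assert not in_range

    def test_invalid_reading_rejected(self):
        curve = _noiseless_curve()
        with pytest.raises(ValueError):
            interpolate_concentration(curve, 1.0, 1.0)


class TestCrossReactivity:
    def test_divide_mode_arithmetic(self):
        assert correct_cross_reactivity(38.0, 0.38, "divide") == pytest.approx(100.0)

    def test_factor_one_is_identity(self):
        assert correct_cross_reactivity(55.0, 1.0) == pytest.approx(55.0)

    def test_modes_are_mutual_inverses(self):
        value = correct_cross_reactivity(
            correct_cross_reactivity(70.0, 0.38, "divide"), 0.38, "multiply"
        )
        assert value == pytest.approx(70.0)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            correct_cross_reactivity(10.0, 0.0)


class TestDilutionConcordance:
    @pytest.mark.parametrize(
        "concs,disparity,passes",
        [
            ((100.0, 100.0), 0.0, True),
            ((100.0, 110.0), 100 * 10 / 105, True),
            ((100.0, 130.0), 100 * 30 / 115, False),
        ],
    )
    def test_disparity_arithmetic(self, concs, disparity, passes):
        out = dilution_concordance(concs)
        assert out["disparity_percent"] == pytest.approx(disparity, rel=1e-9)
        assert out["qc_pass"] is passes

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            dilution_concordance([100.0])


class TestUnitConversion:
    def test_exposed_cells_printed_pair(self):
        assert convert_units(1.68) == pytest.approx(75.6, rel=0.005)

    def test_control_cells_printed_pair(self):
        assert convert_units(1.46) == pytest.approx(65.9, rel=0.01)

    def test_round_trip_identity(self):
        assert convert_pg_per_ug_to_nm(convert_units(1.68)) == pytest.approx(1.68, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            convert_units(0.0)


class TestIpEfficiency:
    def test_basic_percentage(self):
        assert ip_efficiency(300, 1000)["efficiency_percent"] == pytest.approx(30.0)

    def test_background_subtraction(self):
        out = ip_efficiency(300, 1000, 50)
        assert out["efficiency_percent"] == pytest.approx(100 * 250 / 950)

    def test_full_recovery_is_hundred_percent(self):
        assert ip_efficiency(1000, 1000)["efficiency_percent"] == pytest.approx(100.0)

    def test_clipping_flagged(self):
        out = ip_efficiency(1200, 1000)
        assert out["efficiency_percent"] == 100.0 and out["clipped"]

    def test_input_below_background_rejected(self):
        with pytest.raises(ValueError):
            ip_efficiency(10, 40, 50)


class TestDotblot:
    def test_exact_linear_points(self):
        out = dotblot_linearity([1, 2, 4], [10.0, 20.0, 40.0])
        assert out["slope"] == pytest.approx(10.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_flat_signal(self):
        out = dotblot_linearity([1, 2, 3], [5.0, 5.0, 5.0])
        assert out["slope"] == pytest.approx(0.0)
        assert out["r_squared"] == pytest.approx(0.0)

    def test_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 5.0])
        y = np.array([3.0, 4.0, 11.0])
        out = dotblot_linearity(x, y)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert out["slope"] == pytest.approx(slope, rel=1e-12)
        assert out["intercept"] == pytest.approx(intercept, rel=1e-12)

    def test_constant_marks_rejected(self):
        with pytest.raises(ValueError):
            dotblot_linearity([2, 2, 2], [1.0, 2.0, 3.0])


def _bands(**overrides):
    bands = {
        f"{probe}_{pos}_{cond}": 100.0
        for probe in ("target", "norm")
        for pos in ("distal", "proximal")
        for cond in ("exposed", "control")
    }
    bands.update(overrides)
    return bands


class TestTruncation:
    def test_symmetric_bands_give_unit_index(self):
        result = truncation_index(_bands())
        assert result.oxidation_index == pytest.approx(1.0)
        assert not result.oxidized

    def test_halved_distal_product_calls_oxidized(self):
        result = truncation_index(_bands(target_distal_exposed=50.0))
        assert result.oxidation_index == pytest.approx(0.5)
        assert result.oxidized

    def test_swapping_conditions_inverts_index(self):
        bands = _bands(target_distal_exposed=50.0, norm_proximal_control=80.0)
        result = truncation_index(bands)
        swapped = {
            k.replace("exposed", "XX").replace("control", "exposed").replace("XX", "control"): v
            for k, v in bands.items()
        }
        inverted = truncation_index(swapped)
        assert inverted.oxidation_index == pytest.approx(1 / result.oxidation_index)

    def test_zero_band_named_in_error(self):
        with pytest.raises(ValueError, match="norm_distal_control"):
            truncation_index(_bands(norm_distal_control=0.0))


class TestLoadingNormalize:
    def test_identical_lanes_give_unity(self):
        assert loading_normalize(10, 5, 10, 5) == pytest.approx(1.0)

    def test_halved_exposed_target(self):
        assert loading_normalize(10, 5, 5, 5) == pytest.approx(2.0)

    def test_lane_scale_invariance(self):
        base = loading_normalize(10, 5, 7, 4)
        scaled = loading_normalize(10 * 3.7, 5 * 3.7, 7, 4)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            loading_normalize(10, 0, 5, 5)
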