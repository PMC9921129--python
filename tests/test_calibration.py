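"""Internal-standard calibration, ICH limits and quantification flags."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rosegc import pipeline as pl
from rosegc.calibration import (
    CalibrationCurve,
    fit_calibration,
    load_curves,
    lod_loq,
    quantify,
    save_curves,
    select_dilution,
    mass_conversion_for,
)
from rosegc.io import Peak, PeakTable
from rosegc.simulate import POLAR_WAX, SampleSpec, simulate_chromatogram


class TestFitCalibration:
    def test_exact_line_recovered(self):
        points = [(c, 2.0 * c * 5.0, 5.0) for c in (0.1, 0.2, 0.4, 0.8)]
        curve = fit_calibration(points)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_single_concentration_rejected(self):
        points = [(0.1, 1.0, 1.0)] * 4
        with pytest.raises(ValueError, match="degenerate|distinct"):
            fit_calibration(points)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_calibration([(0.1, 1.0, 1.0), (0.2, 2.0, 1.0)])

    def test_zero_is_area_rejected_naming_injection(self):
        points = [(0.1, 1.0, 1.0), (0.2, 2.0, 0.0), (0.4, 4.0, 1.0)]
        with pytest.raises(ValueError, match="injection 2"):
            fit_calibration(points)

    def test_recovers_generator_response_factor(self, polar_library):
        """Simulated six-level batch at the printed range: slope within 5% of RF/IS."""
        e = polar_library.entry("alpha-pinene", "polar_wax")
        is_conc = 10 * 100.16 / 1000.0
        points = []
        for i in range(6):
            c = e.range_low * (e.range_high / e.range_low) ** (i / 5)
            spec = SampleSpec(concentrations={"alpha_pinene": c}, noise_sd=1e-4, seed=i)
            table = pl.process_trace(simulate_chromatogram(spec, POLAR_WAX), polar_library)
            points.append((c, table.get("alpha-pinene").area, table.get("cis-3-hexen-1-ol").area))
        curve = fit_calibration(points, analyte="alpha-pinene")
        assert curve.slope == pytest.approx(1.0 / is_conc, rel=0.05)


class TestLodLoq:
    def test_perfect_calibration_gives_zero_limits(self):
        curve = CalibrationCurve("x", slope=2.0, intercept=0.0, residual_sd=0.0,
                                 range_low=0.1, range_high=1.0, r_squared=1.0)
        assert lod_loq(curve) == (0.0, 0.0)

    def test_direct_formula_arithmetic(self):
        curve = CalibrationCurve("x", slope=10.0, intercept=0.0, residual_sd=1.0,
                                 range_low=0.1, range_high=1.0, r_squared=1.0,
                                 mass_conversion=1.0)
        lod, loq = lod_loq(curve)
        assert lod == pytest.approx(0.33)
        assert loq == pytest.approx(1.0)

    def test_printed_alpha_pinene_pair_consistent_with_ich_ratio(self):
        """A σ/S giving LoD 0.96 ng must give LoQ 2.90 ng within rounding."""
        mc = mass_conversion_for(50.0)  # polar column: 1 µL at split 1:50
        sigma_over_s = 0.96 / (3.3 * mc)
        curve = CalibrationCurve("alpha-pinene", slope=1.0, intercept=0.0,
                                 residual_sd=sigma_over_s, range_low=0.0062,
                                 range_high=0.6202, r_squared=1.0, mass_conversion=mc)
        lod, loq = lod_loq(curve)
        assert lod == pytest.approx(0.96)
        assert loq == pytest.approx(2.90, abs=0.02)

    def test_non_positive_slope_rejected(self):
        curve = CalibrationCurve("x", slope=0.0, intercept=0.0, residual_sd=1.0,
                                 range_low=0.1, range_high=1.0, r_squared=1.0)
        with pytest.raises(ValueError, match="slope"):
            lod_loq(curve)

    @given(st.floats(min_value=1e-6, max_value=10.0), st.floats(min_value=1e-3, max_value=100.0))
    def test_loq_over_lod_is_exactly_10_over_33(self, sigma, slope):
        curve = CalibrationCurve("x", slope=slope, intercept=0.0, residual_sd=sigma,
                                 range_low=0.1, range_high=1.0, r_squared=1.0)
        lod, loq = lod_loq(curve)
        assert loq / lod == pytest.approx(10.0 / 3.3)


def _curve(slope=2.0, intercept=0.0, sd=0.001, low=0.01, high=1.0):
    c = CalibrationCurve("a", slope=slope, intercept=intercept, residual_sd=sd,
                         range_low=low, range_high=high, r_squared=1.0)
    return c


def _assigned_table(entries):
    peaks = [Peak(rt, area=a, assigned_analyte=name) for rt, a, name in entries]
    return PeakTable(peaks, {"column_id": "polar_wax", "internal_standard": "is"})


class TestQuantify:
    def test_on_curve_ratio_recovers_concentration_with_dilution(self):
        curves = {"a": _curve()}
        conc_inj = 0.25
        table = _assigned_table([(10.0, 2.0 * conc_inj * 7.0, "a"), (24.0, 7.0, "is")])
        (res,) = quantify(table, curves, dilution_factor=10.0, analytes=["a"])
        assert res.flag == "ok"
        assert res.concentration == pytest.approx(2.5, rel=1e-9)

    def test_below_loq_has_flag_and_no_numeric_concentration(self):
        curves = {"a": _curve(sd=0.1)}  # LoQ-equivalent conc = 10*0.1/2 = 0.5
        table = _assigned_table([(10.0, 2.0 * 0.1 * 7.0, "a"), (24.0, 7.0, "is")])
        (res,) = quantify(table, curves, dilution_factor=10.0, analytes=["a"])
        assert res.flag == "below_loq"
        assert res.concentration is None

    def test_above_range_taken_from_higher_dilution(self):
        curves = {"a": _curve(high=0.5)}
        minor = _assigned_table([(10.0, 2.0 * 0.9 * 7.0, "a"), (24.0, 7.0, "is")])
        major = _assigned_table([(10.0, 2.0 * 0.018 * 7.0, "a"), (24.0, 7.0, "is")])
        r10 = quantify(minor, curves, dilution_factor=10.0, analytes=["a"])
        r500 = quantify(major, curves, dilution_factor=500.0, analytes=["a"])
        assert r10[0].flag == "above_range"
        merged = select_dilution(r10, r500)
        assert merged[0].dilution_factor == 500.0
        assert merged[0].concentration == pytest.approx(9.0, rel=1e-6)

    def test_missing_curve_reports_error_entry_but_computes_others(self):
        curves = {"a": _curve()}
        table = _assigned_table([(10.0, 1.4, "a"), (12.0, 1.0, "b"), (24.0, 7.0, "is")])
        results = quantify(table, curves, dilution_factor=1.0, analytes=["a", "b"])
        flags = {r.analyte: r.flag for r in results}
        assert flags["b"] == "missing_curve"
        assert flags["a"] in ("ok", "below_loq")

    def test_missing_internal_standard_rejected(self):
        table = PeakTable([Peak(10.0, area=1.0, assigned_analyte="a")],
                          {"column_id": "polar_wax", "internal_standard": "is"})
        with pytest.raises(ValueError, match="[Ii]nternal"):
            quantify(table, {"a": _curve()}, dilution_factor=1.0)

    def test_curves_yaml_round_trip(self, tmp_path):
        curves = {"a": _curve(), "b": _curve(slope=3.0)}
        save_curves(curves, tmp_path / "curves.yaml")
        back = load_curves(tmp_path / "curves.yaml")
        assert back["b"].slope == pytest.approx(3.0)
        assert back["a"].range_high == pytest.approx(1.0)


class TestRoundTripRecovery:
    def test_simulate_detect_calibrate_quantify_within_5_percent(self, polar_library):
        """Parameter-recovery loop at high SNR: every concentration within 5%."""
        curves = pl.run_calibration("polar_wax", seed=17, library=polar_library)
        truth = {"geraniol": 0.05, "citronellol": 0.2, "linalool": 0.02,
                 "alpha_pinene": 0.1, "eugenol": 0.01}
        spec = SampleSpec(concentrations=truth, noise_sd=1e-4, seed=99)
        table = pl.process_trace(simulate_chromatogram(spec, POLAR_WAX), polar_library)
        results = quantify(table, curves, dilution_factor=1.0,
                           internal_standard="cis-3-hexen-1-ol")
        by_name = {r.analyte: r for r in results}
        for compound, c in truth.items():
            name = polar_library.compounds("polar_wax")[compound][0].name
            assert by_name[name].concentration == pytest.approx(c, rel=0.05)
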