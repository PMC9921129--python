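"""Generator ground truth: determinism, area linearity, presets, ladders."""

import numpy as np
import pytest

from rosegc import pipeline as pl
from rosegc.calibration import fit_calibration
from rosegc.retention import compute_retention_index
from rosegc.simulate import (
    CHIRAL_CD,
    POLAR_WAX,
    PeakShapeModel,
    SampleSpec,
    make_sample_spec,
    simulate_alkane_ladder,
    simulate_chromatogram,
    simulate_validation_batch,
)


class TestSampleSpecs:
    def test_unknown_profile_lists_presets(self):
        with pytest.raises(ValueError, match="authentic_rose"):
            make_sample_spec("lavender", 1)

    def test_authentic_preset_rose_oxide_strongly_minus(self):
        spec = make_sample_spec("authentic_rose", 7)
        f = spec.enantiomer_fractions["rose_oxide"]
        # (+) elutes first; EE toward the second-eluting (−) form >= 0.9
        assert (1 - f) - f >= 0.9

    def test_adulterant_preset_rose_oxide_excess_015_toward_plus(self):
        spec = make_sample_spec("geranium_adulterant", 7)
        f = spec.enantiomer_fractions["rose_oxide"]
        assert f == pytest.approx(0.575)
        assert (f - (1 - f)) == pytest.approx(0.15)

    def test_adulterant_has_no_farnesol_but_authentic_does(self):
        assert make_sample_spec("geranium_adulterant", 1).concentrations["farnesol"] == 0.0
        assert make_sample_spec("authentic_rose", 1).concentrations["farnesol"] > 0

    def test_authentic_main_constituents_are_nerol_and_geraniol(self):
        conc = make_sample_spec("authentic_rose", 1).concentrations
        top = sorted(conc, key=conc.get, reverse=True)[:3]
        assert "geraniol" in top and "nerol" in top

    def test_custom_preset_is_blank(self):
        spec = make_sample_spec("custom", 7)
        spec.noise_sd = 0.0
        spec.drift_amplitude = 0.0
        chrom = simulate_chromatogram(spec, POLAR_WAX)
        assert np.all(chrom.intensity == 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SampleSpec(concentrations={"geraniol": -1.0})

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            SampleSpec(enantiomer_fractions={"linalool": 1.2})

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = make_sample_spec("geranium_adulterant", 9)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = SampleSpec.from_yaml(tmp_path / "spec.yaml")
        assert back == spec


class TestChromatogramSimulation:
    def test_bit_identical_under_same_seed(self):
        a = simulate_chromatogram(make_sample_spec("authentic_rose", 42), POLAR_WAX)
        b = simulate_chromatogram(make_sample_spec("authentic_rose", 42), POLAR_WAX)
        assert np.array_equal(a.intensity, b.intensity)

    def test_different_seed_differs(self):
        a = simulate_chromatogram(make_sample_spec("authentic_rose", 42), POLAR_WAX)
        b = simulate_chromatogram(make_sample_spec("authentic_rose", 43), POLAR_WAX)
        assert not np.array_equal(a.intensity, b.intensity)

    @pytest.mark.parametrize("shape_kwargs", [
        {"shape": "gaussian", "fwhm": 0.04},
        {"shape": "emg", "fwhm": 0.04, "emg_tau": 0.02},
    ])
    def test_peak_area_equals_response_factor_times_concentration(self, shape_kwargs):
        """Closed-form oracle: a unit-area profile scaled by RF·c integrates to RF·c."""
        conc = 0.25
        spec = SampleSpec(concentrations={"geraniol": conc}, noise_sd=0.0,
                          drift_amplitude=0.0, is_concentration_mm=0.0)
        shape = PeakShapeModel(response_factor=3.0, **shape_kwargs)
        chrom = simulate_chromatogram(spec, POLAR_WAX, shapes=shape)
        area = float(np.trapezoid(chrom.intensity, chrom.time))
        assert area == pytest.approx(3.0 * conc, rel=5e-3)

    def test_gaussian_amplitude_matches_closed_form(self):
        conc = 0.1
        spec = SampleSpec(concentrations={"geraniol": conc}, noise_sd=0.0,
                          drift_amplitude=0.0, is_concentration_mm=0.0)
        shape = PeakShapeModel(fwhm=0.04)
        chrom = simulate_chromatogram(spec, POLAR_WAX, shapes=shape)
        expected_height = conc / (shape.sigma * np.sqrt(2 * np.pi))
        assert chrom.intensity.max() == pytest.approx(expected_height, rel=1e-3)

    def test_unknown_analyte_rejected_by_name(self):
        spec = SampleSpec(concentrations={"menthol": 0.1})
        with pytest.raises(ValueError, match="menthol"):
            simulate_chromatogram(spec, POLAR_WAX)

    def test_enantiomer_areas_sum_to_group_total(self):
        """Splitting a group must conserve the compound's total area."""
        total = 0.08
        spec = SampleSpec(concentrations={"linalool": total},
                          enantiomer_fractions={"linalool": 0.37},
                          noise_sd=0.0, drift_amplitude=0.0, is_concentration_mm=0.0)
        chrom = simulate_chromatogram(spec, CHIRAL_CD)
        area = float(np.trapezoid(chrom.intensity, chrom.time))
        assert area == pytest.approx(total, rel=5e-3)

    def test_area_linearity_over_calibration_range(self, polar_library):
        """Noiseless six-level fit over the printed range is linear (R² > 0.999)."""
        e = polar_library.entry("alpha-pinene", "polar_wax")
        points = []
        for i in range(6):
            c = e.range_low * (e.range_high / e.range_low) ** (i / 5)
            spec = SampleSpec(concentrations={"alpha_pinene": c}, noise_sd=0.0,
                              drift_amplitude=0.0)
            chrom = simulate_chromatogram(spec, POLAR_WAX)
            table = pl.process_trace(chrom, polar_library)
            points.append((c, table.get("alpha-pinene").area,
                           table.get("cis-3-hexen-1-ol").area))
        curve = fit_calibration(points, analyte="alpha-pinene")
        assert curve.r_squared > 0.999


class TestAlkaneLadder:
    def test_c8_to_c20_gives_13_increasing_rungs(self):
        chrom, ladder = simulate_alkane_ladder(POLAR_WAX, (8, 20))
        assert len(ladder.rungs) == 13
        rts = ladder.retention_times
        assert np.all(np.diff(rts) > 0)
        table = pl.process_trace(chrom, min_snr=5)
        assert len(table) == 13

    def test_ri_at_each_rung_is_100n(self):
        _, ladder = simulate_alkane_ladder(POLAR_WAX)
        for n, rt in ladder.rungs:
            assert compute_retention_index(rt, ladder) == pytest.approx(100 * n, abs=1e-9)

    def test_non_bracketing_range_warns(self):
        _, ladder = simulate_alkane_ladder(POLAR_WAX, (10, 12))
        assert ladder.warnings

    def test_default_ranges_bracket_all_analytes(self):
        for method in (POLAR_WAX, CHIRAL_CD):
            _, ladder = simulate_alkane_ladder(method)
            assert not ladder.warnings

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="n_min < n_max"):
            simulate_alkane_ladder(POLAR_WAX, (12, 12))


class TestValidationBatch:
    def test_batch_size_is_days_times_replicates_times_levels(self):
        levels = {"QC_low": {"geraniol": 0.01}, "QC_med": {"geraniol": 0.03},
                  "QC_high": {"geraniol": 0.07}}
        batch = simulate_validation_batch(levels, days=5, replicates=2, seed=0)
        assert len(batch) == 30

    def test_noiseless_jitter_free_batch_recovers_truth_exactly(self, polar_library):
        batch = simulate_validation_batch(
            [{"alpha_pinene": 0.1, "geraniol": 0.05}], days=2, replicates=2, seed=1,
            day_rt_sd=0.0, day_rf_sd=0.0, injection_rf_sd=0.0, noise_sd=0.0,
        )
        is_conc = 10 * 100.16 / 1000.0
        for inj in batch:
            table = pl.process_trace(inj.chromatogram, polar_library)
            ratios = pl.response_ratios(table, polar_library)
            assert ratios["alpha-pinene"] == pytest.approx(0.1 / is_conc, rel=5e-3)
            assert ratios["geraniol"] == pytest.approx(0.05 / is_conc, rel=5e-3)

    def test_day_rt_jitter_keeps_all_peaks_assignable(self, polar_library):
        batch = simulate_validation_batch(
            [{"alpha_pinene": 0.1, "geraniol": 0.05, "linalool": 0.02}],
            days=5, replicates=1, seed=3, day_rt_sd=0.005,
        )
        simulated = {"alpha-pinene", "geraniol", "linalool", "cis-3-hexen-1-ol"}
        for inj in batch:
            table = pl.process_trace(inj.chromatogram, polar_library)
            assert simulated.isdisjoint(table.metadata["absent_analytes"])
            for name in simulated:
                assert table.get(name) is not None
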