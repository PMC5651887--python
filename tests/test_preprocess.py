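"""Preprocessing-stage tests against analytic constructions."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryoraman import preprocess, synthetic
from embryoraman.errors import CalibrationError, NormalizationError
from embryoraman.io_formats import LabeledCohort, Spectrum
from embryoraman.preprocess import (
    PreprocessConfig,
    baseline_correct,
    calibrate,
    despike,
    normalize_max,
    run_chain,
    subtract_water,
)
from embryoraman.synthetic import BandSpec, SimConfig

from conftest import gaussian


def _replaced_channels(spectrum):
    m = re.search(r"replaced=\[(.*?)\]", spectrum.processing_log[-1])
    body = m.group(1) if m else ""
    return [int(v) for v in body.split(",") if v.strip()]


class TestDespike:
    def test_noop_on_spike_free_spectrum(self, axis):
        rng = np.random.default_rng(0)
        y = gaussian(axis, 1000.0, 9.0, 0.5) + rng.normal(0, 0.01, axis.size)
        out = despike(Spectrum("c", axis, y), 8.0)
        assert np.array_equal(out.intensity, y)

    def test_restores_spike_and_touches_nothing_else(self, axis):
        rng = np.random.default_rng(1)
        clean = gaussian(axis, 1000.0, 9.0, 0.5) + rng.normal(0, 0.01, axis.size)
        spiked = clean.copy()
        spiked[400] += 50.0 * max(abs(clean[400]), 0.05)
        out = despike(Spectrum("s", axis, spiked), 8.0)
        assert abs(out.intensity[400] - clean[400]) < 3 * 0.01
        replaced = _replaced_channels(out)
        assert replaced == [400]
        keep = np.ones(axis.size, bool)
        keep[replaced] = False
        assert np.array_equal(out.intensity[keep], spiked[keep])

    def test_constant_spectrum_unchanged(self, axis):
        y = np.full(axis.size, 3.0)
        out = despike(Spectrum("k", axis, y), 8.0)
        assert np.array_equal(out.intensity, y)

    def test_short_spectrum_skipped_with_warning(self):
        s = Spectrum("tiny", [1.0, 2.0, 3.0], [0.0, 9.0, 0.0])
        out = despike(s, 8.0)
        assert np.array_equal(out.intensity, s.intensity)
        assert any("despike-skipped" in t for t in out.processing_log)


class TestCalibrate:
    def test_identity_when_toluene_on_reference_shifts(self, axis):
        cfg = SimConfig(noise_sd=0.0)
        toluene, _ = synthetic.generate_references(cfg, np.random.default_rng(0))
        s = Spectrum("x", axis, np.ones_like(axis))
        out, cal = calibrate(s, toluene)
        assert cal.residual_rms < 0.1
        assert abs(cal.coefficients[0] - 1.0) < 1e-3  # slope
        assert abs(cal.coefficients[1]) < 1e-3 * 1800  # intercept, axis scale
        assert np.max(np.abs(out.shift - axis)) < 0.1

    def test_linear_distortion_inverted_within_tolerance(self, axis):
        cfg = SimConfig(noise_sd=0.0, pixel_map=(1.01, 3.0))
        toluene, _ = synthetic.generate_references(cfg, np.random.default_rng(0))
        s = Spectrum("x", axis, np.ones_like(axis))
        out, cal = calibrate(s, toluene)
        true_axis = (axis - 3.0) / 1.01
        assert np.max(np.abs(out.shift - true_axis)) < 0.2

    def test_single_reference_peak_raises(self, axis):
        y = gaussian(axis, 1003.6, 3.0, 1.0)
        toluene = Spectrum("t", axis, y)
        with pytest.raises(CalibrationError, match="matched only"):
            calibrate(Spectrum("x", axis, np.ones_like(axis)), toluene)


class TestSubtractWater:
    def test_unit_mode_inverts_additive_model(self, axis):
        water_y = gaussian(axis, 1640.0, 180.0, 0.25)
        signal = gaussian(axis, 1000.0, 9.0, 0.5)
        s = Spectrum("s", axis, signal + water_y)
        out = subtract_water(s, Spectrum("w", axis, water_y), mode="unit")
        np.testing.assert_allclose(out.intensity, signal, atol=1e-12)

    def test_lsq_recovers_scale(self, axis):
        rng = np.random.default_rng(3)
        water_y = gaussian(axis, 1640.0, 180.0, 0.25) + gaussian(axis, 760.0, 260.0, 0.15)
        signal = gaussian(axis, 1000.0, 9.0, 0.5)  # ~0 in the 1620-1800 window
        s = Spectrum("s", axis, signal + 0.7 * water_y + rng.normal(0, 1e-4, axis.size))
        out = subtract_water(
            s, Spectrum("w", axis, water_y), mode="lsq", fit_window=(1620.0, 1800.0)
        )
        alpha = float(re.search(r"alpha=([\d.e+-]+)", out.processing_log[-1]).group(1))
        assert abs(alpha - 0.7) < 0.02

    def test_zero_water_is_identity(self, axis):
        s = Spectrum("s", axis, gaussian(axis, 1000.0, 9.0, 0.5))
        out = subtract_water(s, Spectrum("w", axis, np.zeros_like(axis)), mode="unit")
        np.testing.assert_array_equal(out.intensity, s.intensity)


class TestBaseline:
    def test_pure_cubic_removed_exactly(self, axis):
        t = (axis - 600.0) / 1200.0
        cubic = 2.0 - 1.5 * t + 0.8 * t**2 - 0.3 * t**3
        out, base = baseline_correct(Spectrum("c", axis, cubic))
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.max(np.abs(cubic))

    def test_cubic_plus_band_decomposition(self, axis):
        t = (axis - 600.0) / 1200.0
        cubic = 2.0 - 1.5 * t + 0.8 * t**2 - 0.3 * t**3
        band = gaussian(axis, 1000.0, 9.0, 0.5)
        out, base = baseline_correct(Spectrum("cb", axis, cubic + band))
        assert abs(out.intensity.max() - 0.5) / 0.5 < 0.05
        assert np.sqrt(np.mean((base - cubic) ** 2)) < 0.02 * np.sqrt(np.mean(cubic**2))

    def test_zero_input_stays_zero(self, axis):
        out, base = baseline_correct(Spectrum("z", axis, np.zeros_like(axis)))
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)
        np.testing.assert_allclose(base, 0.0, atol=1e-12)


class TestNormalize:
    def test_max_is_one(self, axis):
        s = Spectrum("n", axis, gaussian(axis, 1000.0, 9.0, 0.37))
        assert normalize_max(s).intensity.max() == 1.0

    def test_idempotent(self, axis):
        s = normalize_max(Spectrum("n", axis, gaussian(axis, 1000.0, 9.0, 0.37)))
        np.testing.assert_array_equal(normalize_max(s).intensity, s.intensity)

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        axis = np.linspace(600.0, 1800.0, 301)
        y = gaussian(axis, 1000.0, 9.0, 0.5) + 0.01
        a = normalize_max(Spectrum("a", axis, y))
        b = normalize_max(Spectrum("b", axis, scale * y))
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_nonpositive_maximum_raises(self, axis):
        with pytest.raises(NormalizationError, match="non-positive"):
            normalize_max(Spectrum("bad", axis, -np.ones_like(axis)))


class TestRunChain:
    def test_full_chain_postconditions(self, default_cohort):
        _, cohort, _, toluene, water = default_cohort
        processed, report = run_chain(cohort, toluene, water)
        assert report["n_out"] == 31
        assert not report["failures"]
        for s in processed.spectra:
            assert s.intensity.max() == pytest.approx(1.0)
            assert any(t.startswith("baseline") for t in s.processing_log)

    def test_noise_free_single_band_end_to_end(self, clean_single_band_config):
        cfg = clean_single_band_config
        rng = np.random.default_rng(0)
        s, _ = synthetic.generate_spectrum(cfg, "pregnant", rng, sample_id="one")
        toluene, _ = synthetic.generate_references(cfg)
        cohort = LabeledCohort([s], {"one": "pregnant"}, cfg.axis)
        processed, report = run_chain(cohort, toluene, None)
        assert not report["failures"]
        expected = gaussian(cfg.axis, 900.0, 8.0, 1.0)
        rms = np.sqrt(np.mean((processed.spectra[0].intensity - expected) ** 2))
        assert rms < 1e-3

    def test_empty_cohort_passes_through(self):
        empty = LabeledCohort([], {}, None)
        out, report = run_chain(empty, None, None)
        assert len(out) == 0
        assert report["n_in"] == 0 and report["n_out"] == 0

    def test_chain_recovers_true_band_ratios(self, default_cohort):
        """Full-chain 900/940 area-ratio recovery within 10% median rel error."""
        from embryoraman import bandfit

        _, cohort, truths, toluene, water = default_cohort
        processed, _ = run_chain(cohort, toluene, water)
        fits = bandfit.fit_cohort(processed)
        features = bandfit.build_features(fits, processed.labels)
        true_ratio = {t.sample_id: t.true_area(900.0) / t.true_area(940.0) for t in truths}
        tab = features.table
        rel = [
            abs(tab.loc[sid, "r900_940"] - true_ratio[sid]) / true_ratio[sid]
            for sid in tab.index
        ]
        assert np.median(rel) < 0.10
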