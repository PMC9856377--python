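"""Unit and property tests for the one-path impedance analysis."""

import numpy as np
import pytest

from epibarrier import (
    DEFAULT_FREQUENCIES,
    DegenerateInputError,
    ImpedanceSpectrum,
    OnePathModel,
    StateError,
    ValidationError,
    correct_bath_resistance,
    epithelial_resistance,
    fit_one_path,
    one_path_impedance,
)
from epibarrier.impedance import grid_search_one_path

from conftest import make_spectrum


class TestCircuitEquation:
    def test_low_frequency_limit_is_total_resistance(self):
        z = one_path_impedance(1e-9, 10, 90, 3e-6)
        assert z.real == pytest.approx(100.0, rel=1e-9)
        assert z.imag == pytest.approx(0.0, abs=1e-6)

    def test_high_frequency_limit_is_subepithelial_resistance(self):
        z = one_path_impedance(1e12, 10, 90, 3e-6)
        assert z.real == pytest.approx(10.0, rel=1e-6)
        assert z.imag == pytest.approx(0.0, abs=1e-6)

    def test_characteristic_frequency_semicircle_apex(self):
        # at f_c = 1/(2 pi R_epi C) the locus sits at the semicircle apex
        f_c = 1.0 / (2 * np.pi * 90 * 3e-6)
        z = one_path_impedance(f_c, 10, 90, 3e-6)
        assert z.real == pytest.approx(55.0, rel=1e-12)
        assert z.imag == pytest.approx(-45.0, rel=1e-12)

    def test_default_grid_spans_study_band(self):
        assert DEFAULT_FREQUENCIES.size == 48
        assert DEFAULT_FREQUENCIES[0] == pytest.approx(1.3)
        assert DEFAULT_FREQUENCIES[-1] == pytest.approx(65e3)

    def test_nyquist_apex_equals_half_repi(self):
        # analytic semicircle property, checked on a dense grid
        f = np.logspace(-2, 7, 20001)
        z = one_path_impedance(f, 10, 90, 3e-6)
        assert np.max(-z.imag) == pytest.approx(45.0, abs=1e-6)
        # exact apex value at f_c
        zc = one_path_impedance(1 / (2 * np.pi * 90 * 3e-6), 10, 90, 3e-6)
        assert -zc.imag == pytest.approx(90.0 / 2.0, abs=1e-9)


class TestBathCorrection:
    def test_zero_correction_only_sets_flag(self):
        spec = make_spectrum(corrected=False)
        out = correct_bath_resistance(spec, 0.0)
        assert out.bath_corrected
        np.testing.assert_array_equal(out.z, spec.z)

    def test_real_part_shifted_imaginary_unchanged(self):
        spec = ImpedanceSpectrum([10.0, 100.0], [110 - 5j, 20 - 1j])
        out = correct_bath_resistance(spec, 10.0)
        np.testing.assert_allclose(out.z.real, [100.0, 10.0])
        np.testing.assert_allclose(out.z.imag, [-5.0, -1.0])

    def test_overlarge_r_bath_rejected(self):
        spec = ImpedanceSpectrum([10.0, 100.0], [110 - 5j, 20 - 1j])
        with pytest.raises(ValidationError):
            correct_bath_resistance(spec, 25.0)

    def test_double_correction_rejected(self):
        spec = make_spectrum(corrected=False)
        once = correct_bath_resistance(spec, 1.0)
        with pytest.raises(StateError):
            correct_bath_resistance(once, 1.0)


class TestEpithelialResistance:
    @pytest.mark.parametrize("r_t,r_sub,expected", [(120, 30, 90), (50, 50, 0)])
    def test_subtraction(self, r_t, r_sub, expected):
        assert epithelial_resistance(r_t, r_sub) == expected

    def test_rt_below_rsub_rejected(self):
        with pytest.raises(ValidationError):
            epithelial_resistance(30, 50)


class TestOnePathFit:
    def test_noiseless_round_trip_machine_precision(self, reference_spectrum):
        fit = OnePathModel(reference_spectrum).fit()
        assert fit.converged
        np.testing.assert_allclose(fit.params, [10.0, 90.0, 3e-6], rtol=1e-6)
        assert fit.r_t == fit.r_sub + fit.r_epi  # exact identity

    def test_intercept_method_close_on_noiseless_data(self, reference_spectrum):
        fit = fit_one_path(reference_spectrum, method="intercept")
        # grid ends are not true limits, so only loose agreement is expected
        assert fit.r_t == pytest.approx(100.0, rel=0.05)
        assert fit.r_sub == pytest.approx(10.0, rel=0.10)

    def test_monotone_identifiability_in_repi(self):
        fitted = []
        for r_epi in np.linspace(20, 200, 10):
            fit = OnePathModel(make_spectrum(r_epi=r_epi)).fit()
            fitted.append(fit.r_epi)
        assert np.all(np.diff(fitted) > 0)

    def test_flat_spectrum_degenerate(self):
        f = DEFAULT_FREQUENCIES
        spec = ImpedanceSpectrum(f, np.full(f.size, 50.0 + 0.0j), bath_corrected=True)
        with pytest.raises(DegenerateInputError):
            OnePathModel(spec).fit()

    def test_too_few_frequencies_rejected(self):
        spec = make_spectrum(freqs=np.logspace(0, 4, 5))
        with pytest.raises(ValidationError):
            OnePathModel(spec).fit()

    def test_narrow_band_rejected(self):
        spec = make_spectrum(freqs=np.linspace(100, 900, 20))
        with pytest.raises(ValidationError):
            OnePathModel(spec).fit()

    def test_noisy_recovery_median_error_small(self, rng):
        errs = []
        for _ in range(30):
            spec = make_spectrum(noise=0.01, rng=rng)
            fit = OnePathModel(spec).fit()
            errs.append(abs(fit.r_epi - 90.0) / 90.0)
        assert np.median(errs) < 0.05

    def test_grid_oracle_confirms_least_squares_optimum(self, rng):
        for _ in range(5):
            r_sub = rng.uniform(5, 40)
            r_epi = rng.uniform(20, 150)
            cap = rng.uniform(1e-6, 8e-6)
            spec = make_spectrum(r_sub=r_sub, r_epi=r_epi, cap=cap)
            ls = OnePathModel(spec).fit()
            grid = grid_search_one_path(spec)
            np.testing.assert_allclose(grid.params, ls.params, rtol=1e-3)

    def test_summary_mentions_parameters(self, reference_spectrum):
        text = OnePathModel(reference_spectrum).fit().summary()
        assert "R_epi" in text and "converged" in text


class TestSpectrumValidation:
    def test_unsorted_frequencies_rejected(self):
        with pytest.raises(ValidationError):
            ImpedanceSpectrum([10.0, 5.0, 20.0], [1 + 0j, 2 + 0j, 3 + 0j])

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValidationError):
            ImpedanceSpectrum([0.0, 5.0], [1 + 0j, 2 + 0j])

    def test_nonfinite_impedance_rejected(self):
        with pytest.raises(ValidationError):
            ImpedanceSpectrum([1.0, 5.0], [np.nan + 0j, 2 + 0j])
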