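"""Spectral estimators: window tiling, normalization, line fits,
form-factor inversion, scatterer spacing and attenuation."""

import numpy as np
import pytest

from qusresp import (estimate_ace, estimate_sas, fit_form_factor,
                     fit_spectral_params, make_pulse, normalized_spectrum,
                     synthesize_rf, tile_windows)
from qusresp.rf_io import RFFrame
from qusresp.rf_simulator import GAUSS_FF_COEF, TissuePhantom
from qusresp.spectral import NormalizedSpectrum, Window, average_spectrum


def synth_spectrum(power_db, f_lo=4.2, f_hi=7.8, fc=6.0, depth=1.0,
                   n=93):
    f = np.linspace(f_lo, f_hi, n)
    y = power_db(f) if callable(power_db) else np.full(n, power_db)
    return NormalizedSpectrum(freqs_mhz=f, power_db=y,
                              band_mhz=(f_lo, f_hi),
                              centre_frequency_mhz=fc,
                              window_depth_cm=depth)


class TestTileWindows:
    def test_default_window_arithmetic(self, frame_factory):
        # 2 mm at fs=40 MHz, c=1540: 2e-3*2*40e6/1540 ~ 104 samples
        fr, _ = frame_factory(0)
        mask = np.ones(fr.samples.shape, dtype=bool)
        grid = tile_windows(mask, fr, overlap=0.94)
        w = grid.windows[0]
        assert w.ax_len == 104
        assert w.lat_len == 10
        assert grid.ax_step == 6      # round(0.06 * 104)
        assert grid.lat_step == 1

    def test_zero_overlap_step_equals_length(self, frame_factory):
        fr, _ = frame_factory(0)
        mask = np.ones(fr.samples.shape, dtype=bool)
        grid = tile_windows(mask, fr, overlap=0.0)
        assert grid.ax_step == grid.windows[0].ax_len
        assert grid.lat_step == grid.windows[0].lat_len

    def test_empty_roi_gives_empty_grid_with_warning(self, frame_factory):
        fr, _ = frame_factory(0)
        mask = np.zeros(fr.samples.shape, dtype=bool)
        with pytest.warns(UserWarning):
            grid = tile_windows(mask, fr)
        assert len(grid) == 0

    def test_windows_respect_inclusion_threshold(self, frame_factory):
        fr, _ = frame_factory(0)
        mask = np.zeros(fr.samples.shape, dtype=bool)
        mask[200:500, 10:40] = True
        grid = tile_windows(mask, fr, overlap=0.5,
                            inclusion_threshold=1.0)
        for w in grid.windows:
            assert mask[w.ax_start:w.ax_start + w.ax_len,
                        w.lat_start:w.lat_start + w.lat_len].all()


class TestNormalizedSpectrum:
    def test_reference_pulse_normalizes_to_zero_db(self, pulse):
        # a window containing exactly the reference pulse: 0 dB flat
        n_ax, n_lines = 104, 10
        samples = np.zeros((600, 40))
        start = 300 + (n_ax - len(pulse.samples)) // 2
        for j in range(12, 12 + n_lines):
            samples[start:start + len(pulse.samples), j] = pulse.samples
        fr = RFFrame(samples=samples, fs=40e6, line_pitch=0.2e-3)
        w = Window(300, 12, n_ax, n_lines, 0.5)
        spec = normalized_spectrum(w, fr, pulse)
        assert np.max(np.abs(spec.power_db)) < 0.5

    def test_amplitude_doubling_adds_six_db(self, pulse, frame_factory):
        fr, grid = frame_factory(0)
        fr2 = RFFrame(samples=2.0 * fr.samples, fs=fr.fs,
                      line_pitch=fr.line_pitch)
        w = grid.windows[5]
        a = normalized_spectrum(w, fr, pulse)
        b = normalized_spectrum(w, fr2, pulse)
        np.testing.assert_allclose(b.power_db - a.power_db,
                                   20 * np.log10(2), atol=1e-9)

    def test_point_scatterer_phantom_spectrum_is_flat(self, pulse,
                                                      frame_factory):
        # diffuse phantom, no attenuation, tiny diameter: mean SS ~ 0
        means = []
        for s in range(8):
            fr, grid = frame_factory(400 + s, diameter=1.0)
            ss = [fit_spectral_params(normalized_spectrum(w, fr, pulse)).ss
                  for w in grid.windows]
            means.append(np.mean(ss))
        assert len(grid) * 8 >= 50
        assert abs(np.mean(means)) < 0.1

    def test_band_is_reference_band(self, pulse, frame_factory):
        fr, grid = frame_factory(0)
        spec = normalized_spectrum(grid.windows[0], fr, pulse)
        assert spec.band_mhz[0] == pytest.approx(4.2, rel=0.01)
        assert spec.band_mhz[1] == pytest.approx(7.8, rel=0.01)


class TestSpectralFit:
    def test_exact_line_recovered(self):
        fit = fit_spectral_params(synth_spectrum(lambda f: 2 * f + 3))
        assert fit.ss == pytest.approx(2.0, abs=1e-10)
        assert fit.si == pytest.approx(3.0, abs=1e-9)
        assert fit.mbf == pytest.approx(15.0, abs=1e-9)

    def test_flat_spectrum(self):
        fit = fit_spectral_params(synth_spectrum(-10.0))
        assert fit.ss == pytest.approx(0.0, abs=1e-12)
        assert fit.si == pytest.approx(-10.0, abs=1e-12)
        assert fit.mbf == pytest.approx(-10.0, abs=1e-12)

    def test_identity_mbf_equals_ss_fc_plus_si(self, pulse, frame_factory):
        fr, grid = frame_factory(0)
        for w in grid.windows[::7]:
            fit = fit_spectral_params(normalized_spectrum(w, fr, pulse))
            assert fit.mbf == pytest.approx(
                fit.ss * 6.0 + fit.si, abs=1e-12)

    def test_slope_estimate_unbiased_under_noise(self):
        # OLS sampling theory: mean slope within 3 SE over 200 replicates
        rng = np.random.default_rng(11)
        f = np.linspace(4.2, 7.8, 93)
        slopes = []
        for _ in range(200):
            spec = synth_spectrum(lambda ff: 2 * ff + 3
                                  + rng.normal(0, 1, len(ff)))
            slopes.append(fit_spectral_params(spec).ss)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.0) < 3 * se

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_spectral_params(synth_spectrum(0.0, n=4))


class TestFormFactor:
    @staticmethod
    def model_db(asd_um, c_db=5.0, c=1540.0):
        def f(fmhz):
            k2 = (2 * np.pi * fmhz * 1e6 / c) ** 2
            return c_db + 10 * np.log10(
                np.exp(-GAUSS_FF_COEF * k2 * (asd_um * 1e-6 / 2) ** 2))
        return f

    def test_noiseless_round_trip_within_2um(self):
        for asd in (60.0, 100.0, 250.0):
            est = fit_form_factor(synth_spectrum(self.model_db(asd)))
            assert est.asd == pytest.approx(asd, abs=2.0)
            assert not est.clipped

    def test_rayleigh_limit_flags_lower_bound(self):
        est = fit_form_factor(synth_spectrum(0.0))
        assert est.asd == 10.0
        assert est.clipped

    def test_concentration_scaling_separable(self):
        a = fit_form_factor(synth_spectrum(self.model_db(100, c_db=5)))
        b = fit_form_factor(synth_spectrum(self.model_db(100, c_db=15)))
        assert b.aac - a.aac == pytest.approx(10.0, abs=0.01)
        assert b.asd == pytest.approx(a.asd, abs=0.5)


class TestSAS:
    def test_ripple_period_maps_to_spacing(self):
        # ripple period 0.77 MHz at c=1540 -> spacing 1000 um
        spec = synth_spectrum(
            lambda f: 10 * np.log10(2.0 + np.cos(2 * np.pi * f / 0.77)))
        est = estimate_sas(spec)
        assert est.present
        assert est.sas == pytest.approx(1000.0, rel=0.03)

    def test_lattice_phantom_per_window_recovery(self, pulse,
                                                 frame_factory):
        # 1 mm lattice, 1% jitter, weak diffuse background
        results = []
        for s in range(4):
            fr, grid = frame_factory(s, density=0.5, spacing=1000.0,
                                     jitter=0.01)
            for w in grid.windows:
                results.append(estimate_sas(
                    normalized_spectrum(w, fr, pulse)))
        assert len(results) >= 50
        detected = [e.sas for e in results if e.present]
        assert len(detected) >= 0.70 * len(results)
        close = np.mean([abs(s - 1000) < 100 for s in detected])
        assert close >= 0.85

    def test_diffuse_phantom_mostly_absent(self, pulse, frame_factory):
        flags = []
        for s in range(4):
            fr, grid = frame_factory(700 + s)
            for w in grid.windows:
                flags.append(estimate_sas(
                    normalized_spectrum(w, fr, pulse)).present)
        assert np.mean(flags) <= 0.2      # absent rate >= 80%

    def test_narrow_band_rejected(self):
        with pytest.raises(ValueError, match="2 MHz"):
            estimate_sas(synth_spectrum(0.0, f_lo=5.0, f_hi=6.5, fc=5.8))


class TestACE:
    def test_exact_linear_decay_recovered(self):
        # power(z, f) = -2 * 0.7 * f * z dB reproduces ace = 0.7 exactly
        spectra = [synth_spectrum(lambda f, z=z: -2 * 0.7 * f * z, depth=z)
                   for z in (1.0, 1.5, 2.0, 2.5)]
        est = estimate_ace(spectra)
        assert est.ace == pytest.approx(0.7, abs=1e-10)
        assert est.n_depth_windows == 4

    def test_identical_spectra_give_zero(self):
        spectra = [synth_spectrum(-5.0, depth=z) for z in (1.0, 2.0, 3.0)]
        assert estimate_ace(spectra).ace == pytest.approx(0.0, abs=1e-12)

    def test_zero_attenuation_phantom(self, pulse):
        fr, grid = _deep_frame(pulse, alpha=0.0, seed=31)
        spectra = [normalized_spectrum(w, fr, pulse) for w in grid.windows]
        assert abs(estimate_ace(spectra).ace) <= 0.1

    def test_insufficient_depth_span_rejected(self):
        spectra = [synth_spectrum(0.0, depth=z) for z in (1.0, 1.2, 1.4)]
        with pytest.raises(ValueError, match="span"):
            estimate_ace(spectra)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            estimate_ace([synth_spectrum(0.0), synth_spectrum(0.0)])


def _deep_frame(pulse, alpha, seed):
    from qusresp.rf_simulator import ScattererPopulation
    ph = TissuePhantom(extent=(40.0, 10.0), populations={
        "background": ScattererPopulation(number_density=25,
                                          effective_diameter=50)},
        attenuation={"background": alpha})
    fr = synthesize_rf(ph, pulse, seed=seed, snr_db=30)
    mask = np.zeros(fr.samples.shape, dtype=bool)
    mask[150:-100, 5:-5] = True
    return fr, tile_windows(mask, fr, overlap=0.5)


class TestFrameAverage:
    def test_average_reduces_to_single_window(self, pulse, frame_factory):
        fr, grid = frame_factory(0)
        w = grid.windows[3]
        a = normalized_spectrum(w, fr, pulse)
        b = average_spectrum([w], fr, pulse)
        np.testing.assert_allclose(a.power_db, b.power_db, atol=1e-12)
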