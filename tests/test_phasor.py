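"""Phasor transform, calibration, filtering and peak readout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import phasorsted as ps
from phasorsted.instrument import InstrumentConfig
from phasorsted.phasor import (analytic_phasor, apply_calibration,
                               compute_calibration, CalibrationFactor,
                               peak_lifetime, phasor_histogram,
                               phasor_transform, spatial_filter, PhasorField)

from conftest import OMEGA, analytic_binned_histogram, image_from_hist


class TestPhasorTransform:
    def test_all_photons_in_first_bin_read_near_zero_lifetime(self, instrument):
        h = np.zeros(instrument.n_bins, dtype=np.int64)
        h[0] = 1000
        f = phasor_transform(image_from_hist(h, instrument))
        # bin-center convention puts the delta at t = bin_width/2
        assert f.g[0, 0] == pytest.approx(1.0, abs=0.03)
        assert f.s[0, 0] == pytest.approx(0.0, abs=0.03)

    def test_uniform_counts_land_exactly_at_origin(self, instrument):
        h = np.full(instrument.n_bins, 37, dtype=np.int64)
        f = phasor_transform(image_from_hist(h, instrument))
        assert f.g[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert f.s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_monoexponential_matches_continuous_closed_form(self, instrument):
        """tau = 2.5 ns: the binned phasor agrees with the closed form
        g = 1/(1+(wt)^2), s = wt/(1+(wt)^2) and with direct numerical
        integration of the continuous decay, within the discretization
        budget of 132 bins."""
        tau = 2.5
        f = phasor_transform(image_from_hist(
            analytic_binned_histogram(tau, instrument), instrument))
        g_cf, s_cf = analytic_phasor(tau, OMEGA)
        assert g_cf == pytest.approx(0.3877, abs=2e-4)
        assert s_cf == pytest.approx(0.4872, abs=2e-4)
        # independent oracle: numerical integration of the wrapped decay
        T = instrument.rep_period
        norm, _ = integrate.quad(lambda t: np.exp(-t / tau), 0, np.inf)
        g_num, _ = integrate.quad(
            lambda t: np.cos(OMEGA * t) * np.exp(-t / tau) / norm, 0, 50 * T,
            limit=400)
        s_num, _ = integrate.quad(
            lambda t: np.sin(OMEGA * t) * np.exp(-t / tau) / norm, 0, 50 * T,
            limit=400)
        assert g_num == pytest.approx(g_cf, abs=1e-6)
        assert s_num == pytest.approx(s_cf, abs=1e-6)
        assert f.g[0, 0] == pytest.approx(g_cf, abs=0.005)
        assert f.s[0, 0] == pytest.approx(s_cf, abs=0.005)

    def test_zero_intensity_pixels_are_flagged_invalid(self, instrument):
        counts = np.zeros((2, 2, instrument.n_bins), dtype=np.int64)
        counts[0, 0, 5] = 10
        img = ps.TCSPCImage(counts=counts, channel_label="x", mode="confocal",
                            sted_power=0.0, instrument=instrument)
        f = phasor_transform(img)
        assert f.valid[0, 0]
        assert not f.valid[1, 1]
        assert np.isnan(f.g[1, 1])

    def test_aliasing_harmonic_is_refused(self, instrument):
        h = np.full(instrument.n_bins, 5, dtype=np.int64)
        with pytest.raises(ValueError, match="alias"):
            phasor_transform(image_from_hist(h, instrument), harmonic=67)


class TestCalibration:
    def test_analytic_reference_yields_identity(self, instrument):
        ref = phasor_transform(image_from_hist(
            analytic_binned_histogram(2.5, instrument), instrument))
        cal = compute_calibration(ref, 2.5)
        # binned reference is within discretization error of analytic
        assert cal.modulation_scale == pytest.approx(1.0, abs=0.01)
        assert cal.phase_shift == pytest.approx(0.0, abs=0.01)

    def test_apply_then_invert_restores_field(self):
        rng = np.random.default_rng(0)
        f = PhasorField(g=rng.uniform(0, 1, (8, 8)), s=rng.uniform(0, 0.5, (8, 8)),
                        intensity=np.ones((8, 8)), omega=OMEGA)
        cal = CalibrationFactor(phase_shift=0.3, modulation_scale=1.2)
        back = apply_calibration(apply_calibration(f, cal), cal.inverse())
        np.testing.assert_allclose(back.g, f.g, atol=1e-12)
        np.testing.assert_allclose(back.s, f.s, atol=1e-12)

    def test_simulated_reference_recovers_analytic_position(self, reference,
                                                            calibration):
        """An IRF-broadened tau = 2.5 ns specimen calibrated against itself
        sits at the closed-form position."""
        f = apply_calibration(phasor_transform(reference), calibration)
        cen = f.centroid()
        g_cf, s_cf = analytic_phasor(2.5, OMEGA)
        assert cen.real == pytest.approx(g_cf, abs=1e-9)
        assert cen.imag == pytest.approx(s_cf, abs=1e-9)

    def test_pure_reflection_calibrates_to_zero_lifetime_point(self, calibration):
        """IRF-only photons (scattering/reflection) map to (1, 0) after
        calibration with the same IRF."""
        refl = ps.simulate_reference(tau=0.0, shape=(64, 64),
                                     photons_per_pixel=500, seed=5)
        f = apply_calibration(phasor_transform(refl), calibration)
        cen = f.centroid()
        assert cen.real == pytest.approx(1.0, abs=0.01)
        assert cen.imag == pytest.approx(0.0, abs=0.01)

    def test_origin_reference_is_rejected(self, instrument):
        h = np.full(instrument.n_bins, 11, dtype=np.int64)  # uniform -> (0,0)
        ref = phasor_transform(image_from_hist(h, instrument))
        with pytest.raises(ValueError, match="origin"):
            compute_calibration(ref, 2.5)


class TestPhasorGeometry:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(tau=st.floats(0.3, 8.0))
    def test_monoexponential_decays_lie_on_universal_circle(self, tau):
        inst = InstrumentConfig()
        f = phasor_transform(image_from_hist(
            analytic_binned_histogram(tau, inst), inst))
        ref = phasor_transform(image_from_hist(
            analytic_binned_histogram(2.5, inst), inst))
        cal = compute_calibration(ref, 2.5)
        fc = apply_calibration(f, cal)
        g, s = fc.g[0, 0], fc.s[0, 0]
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-3)

    def test_biexponential_decays_fall_strictly_inside_circle(self, instrument):
        h = (analytic_binned_histogram(1.0, instrument)
             + analytic_binned_histogram(4.0, instrument))
        f = phasor_transform(image_from_hist(h, instrument))
        g, s = f.g[0, 0], f.s[0, 0]
        assert (g - 0.5) ** 2 + s**2 < 0.25 - 1e-3

    def test_mixture_phasor_is_photon_weighted_average(self, instrument):
        """Linear property: a pixel holding photons of two dyes sits at the
        photon-weighted mean of the pure phasors (exact in expectation)."""
        ha = analytic_binned_histogram(2.2, instrument, total=3e8)
        hb = analytic_binned_histogram(3.2, instrument, total=7e8)
        fa = phasor_transform(image_from_hist(ha, instrument))
        fb = phasor_transform(image_from_hist(hb, instrument))
        fm = phasor_transform(image_from_hist(ha + hb, instrument))
        wa, wb = ha.sum(), hb.sum()
        z_exp = (wa * fa.z[0, 0] + wb * fb.z[0, 0]) / (wa + wb)
        assert fm.z[0, 0] == pytest.approx(z_exp, abs=1e-9)

    def test_phase_angle_increases_with_lifetime(self, instrument):
        angles = []
        for tau in (0.5, 1.0, 2.0, 3.5, 6.0):
            f = phasor_transform(image_from_hist(
                analytic_binned_histogram(tau, instrument), instrument))
            angles.append(np.arctan2(f.s[0, 0], f.g[0, 0]))
        assert np.all(np.diff(angles) > 0)


class TestSpatialFilter:
    def _noisy_uniform_field(self, n_photons=100, shape=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        g0, s0 = analytic_phasor(2.5, OMEGA)
        # Monte-Carlo phasor noise at ~n_photons per pixel
        n = rng.poisson(n_photons, shape)
        t = rng.exponential(2.5, size=(int(n.max()), *shape))
        mask = np.arange(int(n.max()))[:, None, None] < n
        w = np.exp(1j * OMEGA * t)
        z = (w * mask).sum(axis=0) / np.maximum(n, 1)
        return PhasorField(g=z.real, s=z.imag, intensity=n.astype(float),
                           omega=OMEGA)

    def test_zero_passes_is_identity(self):
        f = self._noisy_uniform_field()
        out = spatial_filter(f, "median", 0)
        np.testing.assert_array_equal(out.g, f.g)
        np.testing.assert_array_equal(out.s, f.s)

    @pytest.mark.parametrize("method,factor", [("median", 2.0), ("wavelet", 1.5)])
    def test_filtering_shrinks_cloud_spread(self, method, factor):
        f = self._noisy_uniform_field()
        out = spatial_filter(f, method, 2)
        assert np.nanstd(out.g) <= np.nanstd(f.g) / factor
        assert np.nanstd(out.s) <= np.nanstd(f.s) / factor

    def test_filter_preserves_region_interiors(self):
        g = np.where(np.arange(32)[None, :] < 16, 0.4, 0.6) * np.ones((32, 32))
        s = np.where(np.arange(32)[None, :] < 16, 0.45, 0.30) * np.ones((32, 32))
        f = PhasorField(g=g, s=s, intensity=np.full((32, 32), 100.0), omega=OMEGA)
        out = spatial_filter(f, "median", 2)
        # noise-free interiors are fixed points of the median
        np.testing.assert_allclose(out.g[:, :13], 0.4, atol=1e-12)
        np.testing.assert_allclose(out.g[:, 19:], 0.6, atol=1e-12)
        np.testing.assert_allclose(out.s[:, :13], 0.45, atol=1e-12)

    def test_intensity_is_untouched(self):
        f = self._noisy_uniform_field()
        out = spatial_filter(f, "median", 3)
        np.testing.assert_array_equal(out.intensity, f.intensity)

    def test_unknown_method_is_rejected(self):
        f = self._noisy_uniform_field()
        with pytest.raises(ValueError, match="unknown"):
            spatial_filter(f, "boxcar", 1)


class TestHistogramAndPeaks:
    def test_single_species_mass_in_one_bin_and_total_counts(self):
        g0, s0 = analytic_phasor(2.5, OMEGA)
        f = PhasorField(g=np.full((10, 10), float(g0)),
                        s=np.full((10, 10), float(s0)),
                        intensity=np.full((10, 10), 50.0), omega=OMEGA)
        h = phasor_histogram(f, bins=64)
        assert h.counts.max() == 100
        assert h.counts.sum() == 100

    def test_threshold_above_max_gives_empty_histogram(self):
        f = PhasorField(g=np.full((4, 4), 0.5), s=np.full((4, 4), 0.3),
                        intensity=np.full((4, 4), 10.0), omega=OMEGA)
        h = phasor_histogram(f, bins=64, intensity_threshold=11.0)
        assert h.counts.sum() == 0
        with pytest.raises(ValueError, match="empty"):
            peak_lifetime(h)

    def test_peak_readout_of_pure_species_recovers_lifetime(self):
        g0, s0 = analytic_phasor(2.5, OMEGA)
        f = PhasorField(g=np.full((8, 8), float(g0)), s=np.full((8, 8), float(s0)),
                        intensity=np.full((8, 8), 100.0), omega=OMEGA)
        assert peak_lifetime(phasor_histogram(f, 256)) == 2.5

    def test_peak_at_zero_lifetime_corner_reads_zero(self):
        f = PhasorField(g=np.full((4, 4), 1.0), s=np.full((4, 4), 0.0),
                        intensity=np.full((4, 4), 10.0), omega=OMEGA)
        assert peak_lifetime(phasor_histogram(f, 64)) == 0.0

    def test_tie_breaks_toward_smallest_g_then_s(self):
        f = PhasorField(g=np.array([[0.3, 0.7]]), s=np.array([[0.4, 0.4]]),
                        intensity=np.array([[10.0, 10.0]]), omega=OMEGA)
        h = phasor_histogram(f, 64)
        tau = peak_lifetime(h)  # equal counts: the smaller-g bin must win
        assert tau > 2.0  # smaller g = longer lifetime

    def test_two_dye_channel_shows_two_local_maxima(self, five_color_confocal_256,
                                                    reference):
        field, hist, _ = ps.process_channel(
            five_color_confocal_256[1], reference, 2.5)
        peaks = ps.histogram_peaks(hist, n_peaks=2)
        assert len(peaks) == 2
        gs = sorted(p[0] for p in peaks)
        assert gs[1] - gs[0] > 0.08  # clearly separated clouds
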