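"""Source-spectrum and axial-PSF physics.

The independent oracles here are closed forms: the coherence length of a
Gaussian band, (2 ln2 / pi) * lambda^2 / delta_lambda, and the brute-force
two-carrier interference sum for a two-line spectrum.
"""

import numpy as np
import pytest

from octgan import spectra as sp


class TestBroadband:
    def test_tophat_plateau_and_rolloff(self, axis):
        spec = sp.make_broadband_spectrum(axis, edge_smoothing_nm=10.0,
                                          shape="tophat")
        lam = axis.wavelengths_nm
        dens = spec.density
        core = dens[(lam > 450) & (lam < 660)]
        assert core.min() > 0.9 * core.max()
        assert dens[lam < 405].max() < 1e-3 * core.max()
        assert dens[lam > 705].max() < 1e-3 * core.max()

    def test_default_band_is_smooth_and_confined(self, axis, broadband):
        lam = axis.wavelengths_nm
        dens = broadband.density
        assert dens[(lam < 425) | (lam > 685)].max() == 0.0
        assert lam[np.argmax(dens)] == pytest.approx(555.0, abs=2.0)
        # ringing-free: PSF secondary maxima stay below 10%
        psf = sp.spectrum_to_psf(broadband, n_depth=2001, depth_span_um=30.0)
        env = psf.intensity_envelope
        peaks = sp.sidelobe_peak_indices(env, rel_height=0.0)
        if len(peaks):
            assert env[peaks].max() < 0.1 * env.max()

    def test_unit_power_normalization(self, broadband):
        assert broadband.total_power == pytest.approx(1.0, abs=1e-12)

    def test_near_monochromatic_line_has_flat_coherence(self, axis):
        spec = sp.make_broadband_spectrum(axis, 550.0, 551.0,
                                          edge_smoothing_nm=0.2)
        psf = sp.spectrum_to_psf(spec, n_depth=501, depth_span_um=20.0)
        env = psf.intensity_envelope
        assert env.min() > 0.95 * env.max()

    def test_band_outside_axis_rejected(self, axis):
        with pytest.raises(ValueError):
            sp.make_broadband_spectrum(axis, 300.0, 685.0)


class TestGappedWindow:
    def test_value_at_peak_centers(self):
        # axis whose grid hits 510 and 635 nm exactly
        axis = sp.SpectralAxis(np.linspace(400.0, 710.0, 1241))
        window = sp.make_gapped_window(axis)
        lam = axis.wavelengths_nm
        for center in (510.0, 635.0):
            idx = np.argmin(np.abs(lam - center))
            assert lam[idx] == center
            assert window.density[idx] == pytest.approx(1.0, abs=1e-6)

    def test_gap_is_deep(self, axis, gapped_window):
        idx = np.argmin(np.abs(axis.wavelengths_nm - 572.5))
        assert gapped_window.density[idx] < 1e-8

    @pytest.mark.parametrize("center,fwhm", [(510.0, 10.0), (635.0, 6.0)])
    def test_fwhm_recovered_by_threshold_crossing(self, axis, gapped_window,
                                                  center, fwhm):
        lam = axis.wavelengths_nm
        near = np.abs(lam - center) < 3 * fwhm
        above = lam[near][gapped_window.density[near] >= 0.5]
        measured = above.max() - above.min()
        assert abs(measured - fwhm) <= axis.pitch_nm

    def test_needs_at_least_one_peak(self):
        with pytest.raises(ValueError):
            sp.SpectralWindow(())


class TestApplyWindow:
    def test_identity_window(self, axis, broadband):
        ones = sp.SourceSpectrum(axis, np.ones(axis.n_samples), is_window=True)
        out = sp.apply_window(broadband, ones)
        np.testing.assert_array_equal(out.density, broadband.density)

    def test_density_vanishes_inside_gap(self, axis, gapped):
        # deep inside the gap the Gaussian tails are numerically negligible
        # (at the 530 nm edge itself the green band's tail is still ~1e-5
        # of the peak: 20 nm is only 4.7 sigma)
        lam = axis.wavelengths_nm
        inside = gapped.density[(lam > 535) & (lam < 615)]
        assert inside.max() < 1e-6 * gapped.density.max()

    def test_power_is_lost_not_renormalized(self, broadband, gapped):
        assert gapped.total_power < broadband.total_power

    def test_axis_mismatch_rejected(self, broadband):
        other = sp.SpectralAxis.uniform(420.0, 700.0, 1024)
        window = sp.make_gapped_window(other)
        with pytest.raises(ValueError):
            sp.apply_window(broadband, window)


def _gaussian_band(axis, center, fwhm):
    s = fwhm / sp.FWHM_SIGMA
    dens = np.exp(-((axis.wavelengths_nm - center) ** 2) / (2 * s * s))
    return sp.SourceSpectrum(axis, dens)


class TestPSF:
    @pytest.mark.parametrize("center,fwhm", [(510.0, 10.0), (635.0, 6.0)])
    def test_gaussian_band_matches_coherence_length(self, axis, center, fwhm):
        """FFT-based PSF FWHM vs the closed-form (2 ln2/pi) lambda^2/dlambda."""
        spec = _gaussian_band(axis, center, fwhm)
        psf = sp.spectrum_to_psf(spec, n_depth=4001, depth_span_um=160.0)
        fit = sp.fit_gaussian_fwhm(psf.depth_um, psf.intensity_envelope)
        expected = sp.gaussian_band_fwhm_um(center, fwhm)
        assert fit.fwhm == pytest.approx(expected, rel=0.02)

    def test_parseval(self, axis, broadband, gapped):
        for spec in (broadband, gapped, _gaussian_band(axis, 510, 10)):
            psf = sp.spectrum_to_psf(spec, n_depth=6001, depth_span_um=400.0)
            assert sp.psf_energy_ratio(psf, spec) == pytest.approx(1.0,
                                                                   rel=1e-6)

    def test_two_line_spectrum_matches_cosine_sum_oracle(self, axis):
        """PSF of two spectral lines == brute-force two-carrier sum."""
        lam = axis.wavelengths_nm
        dens = np.zeros_like(lam)
        i1 = np.argmin(np.abs(lam - 510.0))
        i2 = np.argmin(np.abs(lam - 635.0))
        dens[i1] = 1.0
        dens[i2] = 0.7
        k1, k2 = 2 * np.pi / lam[i2], 2 * np.pi / lam[i1]  # ascending
        k = np.linspace(k1 - 5e-4, k2 + 5e-4, 2048)
        s_k = np.zeros_like(k)
        s_k[np.argmin(np.abs(k - k1))] = 0.7
        s_k[np.argmin(np.abs(k - k2))] = 1.0
        z_um = np.linspace(-20.0, 20.0, 2001)
        gamma = sp.coherence_from_k_density(k, s_k, z_um)
        # independent oracle: direct summation of the two carriers
        z_nm = z_um * 1e3
        ka = k[np.argmin(np.abs(k - k1))]
        kb = k[np.argmin(np.abs(k - k2))]
        oracle = np.abs(0.7 * np.exp(2j * ka * z_nm)
                        + 1.0 * np.exp(2j * kb * z_nm))
        env = np.abs(gamma)
        np.testing.assert_allclose(env / env.max(), oracle / oracle.max(),
                                   atol=1e-6)

    def test_gapped_sidelobe_spacing_matches_beat(self, gapped):
        psf = sp.spectrum_to_psf(gapped, n_depth=8001, depth_span_um=60.0)
        env = psf.intensity_envelope
        peaks = sp.sidelobe_peak_indices(env, rel_height=0.1)
        assert len(peaks) >= 2
        dz = psf.depth_um[1] - psf.depth_um[0]
        spacing = np.diff(np.sort(psf.depth_um[peaks]))
        beat_um = np.pi / (2 * np.pi / 510.0 - 2 * np.pi / 635.0) / 1e3
        # lobes recur at the two-carrier beat period
        core = spacing[np.abs(spacing - beat_um) < beat_um / 2]
        assert len(core) >= 2
        assert np.all(np.abs(core - beat_um) <= beat_um * 0.1 + dz)

    def test_bandwidth_monotonicity(self, axis):
        """Widening a Gaussian band strictly narrows the axial PSF."""
        widths = [2.0, 5.0, 10.0, 20.0, 40.0]
        fwhms = []
        for bw in widths:
            psf = sp.spectrum_to_psf(_gaussian_band(axis, 550.0, bw),
                                     n_depth=4001, depth_span_um=300.0)
            fit = sp.fit_gaussian_fwhm(psf.depth_um, psf.intensity_envelope)
            fwhms.append(fit.fwhm)
        assert all(a > b for a, b in zip(fwhms, fwhms[1:]))

    def test_gapped_wider_than_broadband_with_sidelobes(self, broadband,
                                                        gapped):
        f_bb = sp.expected_axial_fwhm_um(broadband)
        f_gap = sp.expected_axial_fwhm_um(gapped)
        assert f_gap > f_bb
        psf_gap = sp.spectrum_to_psf(gapped, n_depth=4001, depth_span_um=80.0)
        psf_bb = sp.spectrum_to_psf(broadband, n_depth=4001, depth_span_um=80.0)
        env_g = psf_gap.intensity_envelope / psf_gap.intensity_envelope.max()
        env_b = psf_bb.intensity_envelope / psf_bb.intensity_envelope.max()
        peaks_g = sp.sidelobe_peak_indices(env_g, rel_height=0.1)
        assert env_g[peaks_g].max() > 0.1
        sec_b = sp.sidelobe_peak_indices(env_b, rel_height=0.0)
        largest_b = env_b[sec_b].max() if len(sec_b) else 0.0
        assert largest_b < env_g[peaks_g].max()

    def test_too_small_span_flagged(self, axis):
        # the 510/10 band's 11.5 um main lobe cannot fit a 4 um window
        spec = _gaussian_band(axis, 510.0, 10.0)
        with pytest.warns(RuntimeWarning):
            psf = sp.spectrum_to_psf(spec, n_depth=101, depth_span_um=4.0)
        assert not psf.main_lobe_contained


class TestGaussianFit:
    def test_exact_gaussian(self):
        z = np.arange(0.0, 64.0)
        prof = np.exp(-((z - 30.0) ** 2) / 2.0)
        fit = sp.fit_gaussian_fwhm(z, prof)
        assert fit.fwhm == pytest.approx(2.3548, abs=1e-3)
        assert fit.fwhm == pytest.approx(sp.FWHM_SIGMA * fit.sigma,
                                         rel=1e-9)
        assert fit.r_squared > 0.999

    def test_constant_offset_absorbed(self):
        z = np.arange(0.0, 64.0)
        prof = np.exp(-((z - 30.0) ** 2) / 2.0) + 0.1
        fit = sp.fit_gaussian_fwhm(z, prof)
        assert fit.fwhm == pytest.approx(2.3548, abs=1e-2)
        assert fit.offset == pytest.approx(0.1, abs=1e-3)

    def test_flat_profile_raises(self):
        with pytest.raises(sp.GaussianFitError):
            sp.fit_gaussian_fwhm(np.arange(32.0), np.ones(32))

    def test_deterministic(self):
        z = np.arange(0.0, 48.0)
        rng = np.random.default_rng(0)
        prof = np.exp(-((z - 20.0) ** 2) / 8.0) + 0.02 * rng.random(48)
        f1 = sp.fit_gaussian_fwhm(z, prof)
        f2 = sp.fit_gaussian_fwhm(z, prof)
        assert f1 == f2


class TestCSVRoundTrip:
    def test_spectrum_csv_round_trip(self, tmp_path, broadband):
        path = tmp_path / "spectrum.csv"
        broadband.to_csv(path)
        back = sp.SourceSpectrum.from_csv(path)
        np.testing.assert_allclose(back.axis.wavelengths_nm,
                                   broadband.axis.wavelengths_nm)
        np.testing.assert_allclose(back.density, broadband.density)
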