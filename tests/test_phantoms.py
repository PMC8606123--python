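"""Phantom builders, the fringe forward model and pair generation."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import correlate

from octgan import spectra as sp
from octgan.phantoms import (
    AcquisitionConfig,
    generate_dataset,
    load_pair,
    make_bead_phantom,
    make_pair,
    make_tape_phantom,
    make_tissue_phantom,
    scatterer_pixel_locations,
    synthesize_fringes,
)


class TestBeadPhantom:
    def test_single_bead(self):
        assert make_bead_phantom(1, seed=0).n_scatterers == 1

    def test_seed_determinism(self):
        a = make_bead_phantom(10, seed=5)
        b = make_bead_phantom(10, seed=5)
        np.testing.assert_array_equal(a.scatterers, b.scatterers)

    def test_pairwise_separation_brute_force(self):
        phantom = make_bead_phantom(20, extent_um=(400.0, 200.0), seed=2)
        pts = phantom.scatterers[:, :2]
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        d[np.diag_indices_from(d)] = np.inf
        assert d.min() >= 5.0 * 1.2

    def test_extent_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_bead_phantom(500, extent_um=(20.0, 15.0), seed=0)


class TestTapePhantom:
    def test_depth_modes_at_spacing(self):
        phantom = make_tape_phantom(n_layers=3, layer_spacing_um=8.0,
                                    scatterers_per_layer=50, seed=1)
        z = phantom.scatterers[:, 1]
        layer_idx = np.round((z - 4.0) / 8.0)
        assert set(layer_idx) == {0.0, 1.0, 2.0}
        for i in range(3):
            members = z[layer_idx == i]
            assert len(members) == 50
            assert members.std() < 0.5
            assert abs(members.mean() - (4.0 + 8.0 * i)) < 0.2

    def test_seed_determinism(self):
        a = make_tape_phantom(seed=9)
        b = make_tape_phantom(seed=9)
        np.testing.assert_array_equal(a.scatterers, b.scatterers)


class TestTissuePhantom:
    def test_layer_counts_proportional_to_density(self):
        bounds = (2.0, 10.0, 18.0, 26.0)
        dens = (3.0, 1.5, 0.5)
        counts = np.zeros(3)
        for seed in range(5):
            phantom = make_tissue_phantom(bounds, dens, seed=seed)
            z = phantom.scatterers[:, 1]
            for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
                counts[i] += ((z >= lo) & (z < hi)).sum()
        counts /= 5
        expected = np.array(dens) * 128.0 * 8.0
        # Poisson error of the 5-realization mean
        assert np.all(np.abs(counts - expected)
                      < 4 * np.sqrt(expected / 5) + 2)

    def test_seed_determinism(self):
        a = make_tissue_phantom(seed=4)
        b = make_tissue_phantom(seed=4)
        np.testing.assert_array_equal(a.scatterers, b.scatterers)


class TestFringes:
    def test_single_scatterer_peaks_at_depth(self, broadband):
        acq = AcquisitionConfig(seed=0, noise_sigma=0.0)
        z_true = 12.0
        phantom = make_bead_phantom(1, seed=1)
        sc = phantom.scatterers.copy()
        sc[0] = [64.0, z_true, 1.0]
        phantom = type(phantom)(sc, "beads", phantom.extent_um)
        from octgan.processing import reconstruct_bscan

        fringes = synthesize_fringes(phantom, broadband, acq)
        bscan = reconstruct_bscan(fringes, acq.axis.wavelengths_nm)
        zpx, xpx = np.unravel_index(np.argmax(bscan.amplitude),
                                    bscan.amplitude.shape)
        assert abs(zpx * bscan.depth_pitch_um - z_true) <= bscan.depth_pitch_um

    def test_noise_only_variance(self, broadband):
        acq = AcquisitionConfig(seed=3, noise_sigma=0.2)
        empty = make_tissue_phantom(seed=0)
        empty = type(empty)(np.zeros((0, 3)), "tissue", empty.extent_um)
        fringes = synthesize_fringes(empty, broadband, acq)
        assert fringes.var() == pytest.approx(0.2**2, rel=0.05)

    def test_linearity_in_reflectivity(self, broadband):
        acq = AcquisitionConfig(seed=0, noise_sigma=0.0)
        phantom = make_bead_phantom(5, seed=7)
        doubled = type(phantom)(
            phantom.scatterers * np.array([1.0, 1.0, 2.0]), "beads",
            phantom.extent_um)
        f1 = synthesize_fringes(phantom, broadband, acq)
        f2 = synthesize_fringes(doubled, broadband, acq)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-9, atol=1e-30)

    def test_peak_amplitudes_proportional_to_reflectivity(self, broadband):
        from octgan.processing import reconstruct_bscan

        acq = AcquisitionConfig(seed=0, noise_sigma=0.0)
        # pixel-aligned depths (equal sub-pixel sampling), distinct depths so
        # the background-subtraction ghost of one bead misses the other
        dz0 = acq.depth_pitch_um
        sc = np.array([[30.0, 20 * dz0, 0.4], [96.0, 40 * dz0, 1.0]])
        phantom = make_bead_phantom(1, seed=0)
        phantom = type(phantom)(sc, "beads", phantom.extent_um)
        fringes = synthesize_fringes(phantom, broadband, acq)
        amp = reconstruct_bscan(fringes, acq.axis.wavelengths_nm).amplitude
        dz = acq.depth_pitch_um
        peaks = []
        for x_um, z_um, _ in sc:
            col = int(x_um / acq.lateral_pitch_um - 0.5)
            zpx = int(round(z_um / dz))
            peaks.append(amp[zpx - 2:zpx + 3, col - 1:col + 2].max())
        assert peaks[0] / peaks[1] == pytest.approx(0.4, rel=0.01)


class TestMakePair:
    def test_identity_window_gives_equal_members(self):
        phantom = make_bead_phantom(4, seed=2)
        acq = AcquisitionConfig(seed=1)
        window = sp.SpectralWindow(((555.0, 4000.0, 1.0),))
        pair = make_pair(phantom, acq, mode="synthetic-gap", window=window)
        # a near-flat window barely modifies the fringes
        ratio = np.abs(pair.input_bscan.pixels - pair.truth_bscan.pixels).max()
        assert ratio < 0.2 * np.abs(pair.truth_bscan.pixels).max()

    def test_input_fwhm_exceeds_truth_fwhm(self, bead_pair):
        phantom, acq, pair = bead_pair
        dz = pair.input_bscan.depth_pitch_um
        locs = scatterer_pixel_locations(pair)
        widths = {"in": [], "tr": []}
        for zpx, xpx in locs:
            depth = np.arange(pair.input_bscan.pixels.shape[0]) * dz
            for key, img in (("in", pair.input_bscan.amplitude),
                             ("tr", pair.truth_bscan.amplitude)):
                try:
                    fit = sp.fit_gaussian_fwhm(depth, img[:, xpx],
                                               center_um=zpx * dz)
                    widths[key].append(fit.fwhm)
                except sp.GaussianFitError:
                    pass
        assert np.mean(widths["in"]) > np.mean(widths["tr"])

    def test_both_modes_share_truth(self):
        phantom = make_bead_phantom(4, seed=6)
        acq = AcquisitionConfig(seed=9)
        a = make_pair(phantom, acq, mode="synthetic-gap")
        b = make_pair(phantom, acq, mode="two-source")
        np.testing.assert_array_equal(a.truth_bscan.pixels,
                                      b.truth_bscan.pixels)

    def test_co_registration_zero_lag(self, noisy_bead_pair):
        _, _, pair = noisy_bead_pair
        pi = pair.input_bscan.amplitude.mean(axis=1)
        pt = pair.truth_bscan.amplitude.mean(axis=1)
        pi = pi - pi.mean()
        pt = pt - pt.mean()
        xc = correlate(pi, pt, mode="full")
        assert np.argmax(xc) == len(pi) - 1

    def test_sidelobe_artifacts_only_in_input(self, bead_pair):
        """Gapped input shows >=2 sidelobes per bead; truth shows none.

        Profiles are restricted to +-8 um around each bead so that other
        beads in the same column do not count as artifacts.
        """
        _, _, pair = bead_pair
        locs = scatterer_pixel_locations(pair)
        amp_in = pair.input_bscan.amplitude
        amp_tr = pair.truth_bscan.amplitude
        dz = pair.input_bscan.depth_pitch_um
        win = int(round(8.0 / dz))
        n_z = amp_in.shape[0]
        for zpx, xpx in locs:
            lo, hi = max(0, zpx - win), min(n_z, zpx + win + 1)
            assert len(sp.sidelobe_peak_indices(amp_in[lo:hi, xpx], 0.1)) >= 2
            assert len(sp.sidelobe_peak_indices(amp_tr[lo:hi, xpx], 0.1)) == 0

    def test_speckle_statistics_in_homogeneous_layer(self):
        """Tissue amplitude inside one layer is Rayleigh-like."""
        phantom = make_tissue_phantom(seed=12)
        acq = AcquisitionConfig(seed=12)
        pair = make_pair(phantom, acq, phantom_id="tissue-t0")
        amp = pair.truth_bscan.amplitude
        dz = pair.truth_bscan.depth_pitch_um
        # interior of the first (densest) layer
        z0, z1 = int(4.0 / dz), int(8.5 / dz)
        layer = amp[z0:z1]
        cv = layer.std() / layer.mean()
        assert 0.4 <= cv <= 0.7
        from scipy.stats import skew

        assert skew(layer.ravel()) > 0.3


class TestGenerateDataset:
    def test_counts_and_manifest(self, tmp_path):
        manifest = generate_dataset(tmp_path / "d", {"beads": 2, "tape": 2,
                                                     "tissue": 2}, seed=0)
        assert len(manifest) == 6
        assert (tmp_path / "d" / "manifest.csv").exists()
        assert (tmp_path / "d" / "config.yaml").exists()
        files = sorted((tmp_path / "d").glob("pair_*.octz"))
        assert len(files) == 6

    def test_split_phantoms_disjoint(self, tmp_path):
        manifest = generate_dataset(tmp_path / "d", {"beads": 8}, seed=1,
                                    test_fraction=0.25)
        train_ids = set(manifest[manifest.split == "train"].phantom_id)
        test_ids = set(manifest[manifest.split == "test"].phantom_id)
        assert train_ids.isdisjoint(test_ids)
        assert len(test_ids) == 2

    def test_same_master_seed_byte_identical_manifest(self, tmp_path):
        generate_dataset(tmp_path / "a", {"beads": 3}, seed=5)
        generate_dataset(tmp_path / "b", {"beads": 3}, seed=5)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
            (tmp_path / "b" / "manifest.csv").read_bytes()

    def test_pairs_load_back(self, tmp_path):
        manifest = generate_dataset(tmp_path / "d", {"tape": 1}, seed=2)
        pair = load_pair(tmp_path / "d" / manifest.iloc[0]["file"])
        assert pair.phantom_kind == "tape"
        assert pair.input_bscan.pixels.shape == (64, 64)
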