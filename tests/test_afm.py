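"""Height-image levelling, masking, volumetrics and oligomer assignment."""

import numpy as np
import pytest
from skimage.measure import label as sk_label

from forcekin import afm
from forcekin.errors import InvalidInputError


def _plane(shape=(120, 120), a=0.01, b=-0.02, c=0.5):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return a * rows + b * cols + c


def _gaussian_blob(shape, r0, c0, height, sigma_px):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return height * np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma_px**2))


ANCHORS = [(5, 5), (5, 110), (110, 60)]


class TestLevelPlane:
    def test_pure_plane_goes_to_zero(self):
        img = afm.HeightMap(_plane(), pixel_size=1.0)
        out = afm.level_plane(img, ANCHORS, patch=1)
        assert np.max(np.abs(out.heights)) < 1e-9

    def test_blob_preserved_when_anchors_off_blob(self):
        blob = _gaussian_blob((120, 120), 60, 30, 3.0, 4.0)
        img = afm.HeightMap(_plane() + blob, pixel_size=1.0)
        out = afm.level_plane(img, ANCHORS, patch=1)
        np.testing.assert_allclose(out.heights, blob, atol=1e-6)

    def test_patch_averaging_suppresses_noise(self, rng):
        noisy = _plane() + rng.normal(0, 0.1, (120, 120))
        img = afm.HeightMap(noisy, pixel_size=1.0)
        out = afm.level_plane(img, ANCHORS, patch=5)
        rows, cols = np.mgrid[0:120, 0:120]
        design = np.column_stack([rows.ravel(), cols.ravel(), np.ones(rows.size)])
        resid_slope, _, _, _ = np.linalg.lstsq(design, out.heights.ravel(), rcond=None)
        assert abs(resid_slope[0]) < 0.01 / 10.0  # >= 10x reduction of the tilt
        assert abs(resid_slope[1]) < 0.02 / 10.0

    def test_collinear_anchors_rejected(self):
        img = afm.HeightMap(_plane(), pixel_size=1.0)
        with pytest.raises(InvalidInputError):
            afm.level_plane(img, [(5, 5), (5, 50), (5, 110)])


class TestSmooth:
    def test_zero_sigma_is_identity(self, rng):
        img = afm.HeightMap(rng.normal(0, 1, (50, 50)), pixel_size=1.0)
        out = afm.smooth(img, 0.0)
        np.testing.assert_array_equal(out.heights, img.heights)

    def test_delta_spike_becomes_unit_kernel(self):
        heights = np.zeros((41, 41))
        heights[20, 20] = 1.0
        out = afm.smooth(afm.HeightMap(heights, 1.0), 2.0)
        assert out.heights.sum() == pytest.approx(1.0, rel=1e-6)
        assert out.heights[20, 20] == pytest.approx(1.0 / (2 * np.pi * 4.0), rel=0.01)

    def test_interior_blob_volume_conserved(self):
        blob = _gaussian_blob((100, 100), 50, 50, 2.0, 5.0)
        out = afm.smooth(afm.HeightMap(blob, 1.0), 1.5)
        assert out.heights.sum() == pytest.approx(blob.sum(), rel=0.01)


class TestMaskParticles:
    def test_threshold_is_half_raw_maximum(self):
        heights = _gaussian_blob((80, 80), 40, 40, 2.0, 4.0)
        img = afm.HeightMap(heights, 1.0)
        labels = afm.mask_particles(img, img)
        np.testing.assert_array_equal(labels > 0, heights > 1.0)

    def test_two_separated_blobs_two_labels(self):
        heights = (_gaussian_blob((100, 100), 30, 30, 2.0, 3.0)
                   + _gaussian_blob((100, 100), 70, 70, 2.0, 3.0))
        img = afm.HeightMap(heights, 1.0)
        labels = afm.mask_particles(img, img)
        assert labels.max() == 2

    def test_counts_synthetic_field(self, rng):
        vols = np.full(50, 40.0)
        img, truth = afm.synth_afm_image(vols, rng, shape=(400, 400),
                                         noise_sigma=0.05, min_separation=16.0)
        leveled = afm.level_plane(img, [(5, 5), (5, 394), (394, 200)])
        smoothed = afm.smooth(leveled, 1.0)
        labels = afm.mask_particles(img, smoothed)
        assert labels.max() == 50

    def test_masking_monotone_in_threshold(self):
        """Raising the threshold never grows any connected component."""
        heights = (_gaussian_blob((100, 100), 30, 30, 2.0, 4.0)
                   + _gaussian_blob((100, 100), 70, 70, 1.6, 4.0))
        low = sk_label(heights > 0.8, connectivity=2)
        high = sk_label(heights > 1.2, connectivity=2)
        assert np.count_nonzero(high) < np.count_nonzero(low)
        assert np.all((high > 0) <= (low > 0))


class TestParticleVolumes:
    def test_box_blob_arithmetic(self):
        heights = np.zeros((40, 40))
        heights[18:23, 18:23] = 2.0  # 5x5 px, 2 nm tall, 1 nm pixels -> 50 nm^3
        img = afm.HeightMap(heights, 1.0)
        labels = afm.mask_particles(img, img)
        records = afm.particle_volumes(labels, img)
        assert len(records) == 1
        assert records[0].volume == pytest.approx(50.0, rel=1e-6)
        assert records[0].pixel_count == 25

    def test_gaussian_blobs_recovered_within_ten_percent(self, rng):
        for vol in (27.0, 54.0):
            img, _ = afm.synth_afm_image(np.full(15, vol), rng, tilt=(0.0, 0.0),
                                         noise_sigma=0.05, min_separation=18.0)
            ny, nx = img.shape
            leveled = afm.level_plane(img, [(5, 5), (5, nx - 6), (ny - 6, nx // 2)])
            labels = afm.mask_particles(img, afm.smooth(leveled, 1.0))
            got = [r.volume for r in afm.particle_volumes(labels, leveled)
                   if not r.touches_border]
            assert np.mean(got) == pytest.approx(vol, rel=0.10)

    def test_border_particle_flagged(self):
        heights = np.zeros((40, 40))
        heights[0:5, 18:23] = 2.0
        img = afm.HeightMap(heights, 1.0)
        labels = afm.mask_particles(img, img)
        records = afm.particle_volumes(labels, img)
        assert records[0].touches_border


class TestVolumePdfAndStates:
    def test_single_volume_pdf(self):
        pdf = afm.volume_pdf([30.0])
        assert pdf.argmax() == pytest.approx(30.0, abs=pdf.grid[1] - pdf.grid[0])
        assert pdf.integral() == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_maxima_located(self, rng):
        vols = np.concatenate([rng.normal(27.0, 2.0, 200), rng.normal(54.0, 2.0, 200)])
        pdf = afm.volume_pdf(vols)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(pdf.density, prominence=0.1 * pdf.density.max())
        locs = np.sort(pdf.grid[peaks])
        assert locs[0] == pytest.approx(27.0, abs=1.0)
        assert locs[-1] == pytest.approx(54.0, abs=1.0)

    def test_single_state_all_assigned(self, rng):
        vols = rng.normal(27.0, 2.0, 100)
        model = afm.assign_oligomer_states(afm.volume_pdf(vols), vols, n_states=1)
        assert model.fractions[0] == 1.0
        assert model.boundaries.size == 0

    def test_equal_mixture_fraction_recovery(self, rng):
        vols = np.concatenate([rng.normal(27.0, 3.0, 200), rng.normal(54.0, 3.0, 200)])
        model = afm.assign_oligomer_states(afm.volume_pdf(vols), vols, n_states=2)
        assert model.fractions[0] == pytest.approx(0.5, abs=0.06)
        assert abs(model.fractions.sum() - 1.0) < 1e-9

    def test_ladder_boundaries_at_midpoints(self, rng):
        """Five oligomer states at 27k nm^3 put boundaries at 27(k+0.5)."""
        centers = 27.0 * np.arange(1, 6)
        vols = np.concatenate([rng.normal(c, 2.5, 120) for c in centers])
        model = afm.assign_oligomer_states(afm.volume_pdf(vols), vols, n_states=5)
        expected = 27.0 * (np.arange(1, 5) + 0.5)
        np.testing.assert_allclose(model.boundaries, expected, atol=2.0)

    def test_degenerate_peaks_merged_with_warning(self, rng):
        vols = rng.normal(27.0, 2.0, 300)
        pdf = afm.volume_pdf(vols)
        with pytest.warns(UserWarning, match="merging"):
            model = afm.assign_oligomer_states(pdf, vols, n_states=2)
        assert model.peak_means.size == 1


class TestSynthImage:
    def test_zero_particles_is_plane_plus_noise(self, rng):
        img, _ = afm.synth_afm_image(np.empty(0), rng, shape=(60, 60),
                                     tilt=(0.01, 0.0), noise_sigma=0.05)
        rows = (np.arange(60)[:, None] + 0.5) * img.pixel_size
        residual = img.heights - 0.01 * rows  # remove the known tilt
        assert abs(residual.mean()) < 0.05
        assert np.std(residual) == pytest.approx(0.05, rel=0.15)

    def test_total_volume_conserved_noiseless(self, rng):
        vols = np.array([27.0, 54.0, 81.0])
        img, truth = afm.synth_afm_image(vols, rng, tilt=(0.0, 0.0), noise_sigma=0.0)
        total = img.heights.sum() * img.pixel_size**2
        assert total == pytest.approx(vols.sum(), rel=0.01)

    def test_seed_determinism(self):
        a, _ = afm.synth_afm_image([27.0] * 5, np.random.default_rng(3))
        b, _ = afm.synth_afm_image([27.0] * 5, np.random.default_rng(3))
        np.testing.assert_array_equal(a.heights, b.heights)
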