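"""Planning-CT <-> pseudo-DECT conversion stages and their round trip."""

import numpy as np
import pytest
from scipy import ndimage

from vncct.calibration import extract_plug_stats
from vncct.image import CTImage, HU_MIN, ROISpec
from vncct.synthetic import (PHANTOM_PLUGS, PhantomSpec, make_couch_fixture,
                             make_digital_phantom, make_planning_patient)
from vncct.transfer import (CouchRemovalParams, DenoiseParams, NoiseModel,
                            add_noise_to_snr, bilateral_denoise,
                            convert_pct_to_pseudo_dect, invert_to_planning_ct,
                            remove_couch, resample_to_dect_frame)


class TestResample:
    def test_geometry_of_output_frame(self):
        pat, _ = make_planning_patient(seed=0)
        out, record = resample_to_dect_frame(pat)
        assert out.voxels.shape == (512, 512)
        assert out.inplane_spacing == pytest.approx(350.0 / 512.0)
        assert out.fov_mm == pytest.approx(350.0)
        assert record.crop_window[2] == 256

    def test_uniform_region_is_preserved_exactly(self):
        vox = np.full((512, 512), HU_MIN, dtype=np.float32)
        vox[100:400, 100:400] = 50.0  # big square body
        pct = CTImage(voxels=vox, spacing_mm=(1.3672, 1.3672))
        out, _ = resample_to_dect_frame(pct)
        center = out.voxels[200:300, 200:300]
        np.testing.assert_allclose(center, 50.0, atol=1e-4)

    def test_impulse_at_centroid_lands_at_output_center(self):
        vox = np.full((512, 512), HU_MIN, dtype=np.float32)
        yy, xx = np.mgrid[0:512, 0:512]
        body = (yy - 256) ** 2 + (xx - 256) ** 2 <= 90 ** 2
        vox[body] = 0.0
        vox[256, 256] = 500.0
        pct = CTImage(voxels=vox, spacing_mm=(1.3672, 1.3672))
        out, _ = resample_to_dect_frame(pct)
        peak = np.unravel_index(np.argmax(out.voxels), out.voxels.shape)
        # analytic coordinate transform: the impulse sits at input pixel
        # centre 256.5 px; the crop window starts at row/col 128, so the
        # output position is (256.5 - 128) * (s_in / s_out) - 0.5
        s_ratio = 1.3672 / (350.0 / 512.0)
        expected = (256.5 - 128.0) * s_ratio - 0.5
        assert abs(peak[0] - expected) <= 1.0
        assert abs(peak[1] - expected) <= 1.0

    def test_empty_body_rejected(self):
        pct = CTImage(voxels=np.full((512, 512), HU_MIN), spacing_mm=(1.3672, 1.3672))
        with pytest.raises(ValueError):
            resample_to_dect_frame(pct)


class TestBilateral:
    def test_uniform_image_unchanged(self):
        img = CTImage(voxels=np.full((64, 64), 57.0), spacing_mm=(1.0, 1.0))
        out = bilateral_denoise(img)
        np.testing.assert_allclose(out.voxels, 57.0, atol=1e-5)

    def test_noise_sd_strictly_reduced(self):
        """White noise on a flat background: the filter always lowers the
        empirical SD (checked over 50 seeds)."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vox = 50.0 + rng.normal(0, 10.0, (48, 48)).astype(np.float32)
            img = CTImage(voxels=vox, spacing_mm=(1.0, 1.0))
            out = bilateral_denoise(img)
            assert out.voxels.std() < vox.std()

    def test_step_edge_position_preserved(self):
        vox = np.full((64, 64), -800.0, dtype=np.float32)
        vox[:, 32:] = 50.0
        img = CTImage(voxels=vox, spacing_mm=(1.0, 1.0))
        out = bilateral_denoise(img)
        profile = out.voxels[32]
        midpoint = -375.0  # halfway between the two levels
        crossing = int(np.argmax(profile > midpoint))
        assert abs(crossing - 32) <= 1
        # far sides essentially untouched (edge-preserving)
        np.testing.assert_allclose(out.voxels[:, :28], -800.0, atol=0.5)
        np.testing.assert_allclose(out.voxels[:, 36:], 50.0, atol=0.5)

    def test_window_size_rule(self):
        assert DenoiseParams(spatial_sigma=2.0).window == 9
        assert DenoiseParams(spatial_sigma=1.5).window == 7

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DenoiseParams(degree_of_smoothing=0.0)


class TestNoise:
    def test_disabled_noise_is_identity(self):
        img = CTImage(voxels=np.full((32, 32), 10.0), spacing_mm=(1.0, 1.0))
        out = add_noise_to_snr(img, NoiseModel(target_snr_db=None))
        np.testing.assert_array_equal(out.voxels, img.voxels)
        out = add_noise_to_snr(img, NoiseModel(target_snr_db=np.inf))
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_measured_snr_hits_40db(self):
        """Uniform image at the water point: the injected noise realises
        40 +/- 0.5 dB measured over 20 seeds."""
        img = CTImage(voxels=np.zeros((200, 200)), spacing_mm=(1.0, 1.0))
        snrs = []
        for seed in range(20):
            out = add_noise_to_snr(img, NoiseModel(target_snr_db=40.0, rng_seed=seed))
            noise_var = np.var(out.voxels - img.voxels)
            snrs.append(10.0 * np.log10(1024.0 ** 2 / noise_var))
        assert np.mean(snrs) == pytest.approx(40.0, abs=0.5)

    def test_same_seed_reproducible(self):
        img = CTImage(voxels=np.zeros((64, 64)), spacing_mm=(1.0, 1.0))
        a = add_noise_to_snr(img, NoiseModel(rng_seed=7))
        b = add_noise_to_snr(img, NoiseModel(rng_seed=7))
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_roi_mean_shift_bounded(self):
        """Noise barely moves the mean of a 1000-pixel uniform region:
        |shift| < 3 sigma/sqrt(1000) in at least 95% of seeds."""
        img = CTImage(voxels=np.zeros((40, 25)), spacing_mm=(1.0, 1.0))
        sigma = 1024.0 / 10 ** (40.0 / 20.0)
        bound = 3 * sigma / np.sqrt(1000.0)
        hits = sum(
            abs(np.mean(add_noise_to_snr(img, NoiseModel(rng_seed=s)).voxels)) < bound
            for s in range(100)
        )
        assert hits >= 95


class TestCouchRemoval:
    def test_fixture_recovered_exactly(self):
        img, truth = make_couch_fixture(body_pixels=15000, couch_pixels=4000, seed=1)
        cleaned, mask = remove_couch(img)
        np.testing.assert_array_equal(mask.mask, truth["body"])
        assert cleaned.voxels[truth["couch"]].max() == HU_MIN
        assert np.count_nonzero(cleaned.voxels > HU_MIN) == 15000

    def test_internal_air_cavities_filled(self):
        img, truth = make_couch_fixture(seed=2)
        vox = img.voxels.copy()
        body_idx = np.argwhere(truth["body"])
        cy, cx = body_idx.mean(axis=0).astype(int)
        vox[cy - 8:cy + 8, cx - 8:cx + 8] = -800.0  # air pocket inside body
        img2 = CTImage(voxels=vox, spacing_mm=img.spacing_mm)
        _, mask = remove_couch(img2)
        assert mask.mask[cy, cx]
        np.testing.assert_array_equal(mask.mask, truth["body"])

    def test_all_air_image_raises(self):
        img = CTImage(voxels=np.full((128, 128), HU_MIN), spacing_mm=(1.0, 1.0))
        with pytest.raises(ValueError, match="no body"):
            remove_couch(img)

    def test_component_size_boundary(self):
        """A body exactly at the minimum size survives; one pixel fewer in
        the threshold direction trips the 'no body found' error."""
        img, truth = make_couch_fixture(body_pixels=6999, couch_pixels=1000, seed=3)
        _, mask = remove_couch(img, CouchRemovalParams(min_component_pixels=6999))
        assert mask.n_pixels == 6999
        with pytest.raises(ValueError, match="no body"):
            remove_couch(img, CouchRemovalParams(min_component_pixels=7000))

    def test_couch_touching_body_is_retained(self):
        """With no gap the couch fuses into the body component and survives
        the size filter — the documented limitation of the algorithm."""
        img, truth = make_couch_fixture(gap_px=0, seed=4)
        _, mask = remove_couch(img)
        assert mask.mask[truth["couch"]].all()

    def test_largest_component_never_deleted(self, rng):
        for _ in range(5):
            vox = np.full((128, 128), HU_MIN, dtype=np.float32)
            yy, xx = np.mgrid[0:128, 0:128]
            r = rng.uniform(40, 55)
            blob = (yy - 64) ** 2 + (xx - 64) ** 2 <= r ** 2
            vox[blob] = 30.0
            _, mask = remove_couch(
                CTImage(voxels=vox, spacing_mm=(1.0, 1.0)),
                CouchRemovalParams(min_component_pixels=int(blob.sum())))
            assert mask.mask[blob].all()


class TestFullConversion:
    def test_phantom_plug_means_match_measured_pseudo_dect(self):
        """Deterministic conversion of the noise-free digital phantom: every
        plug ROI mean lands within 2 HU of the measured pseudo-DECT value
        for that plug."""
        spec = PhantomSpec(noise_scale=0.0, n_slices=1)
        phantom, rois = make_digital_phantom(spec, domain="planning")
        pseudo, record = convert_pct_to_pseudo_dect(
            phantom, noise=NoiseModel(target_snr_db=None))
        mapped = [ROISpec(center_mm=record.map_point_mm(r.center_mm),
                          radius_mm=r.radius_mm, slice_range=(0,), label=r.label)
                  for r in rois]
        stats = extract_plug_stats(pseudo, mapped)
        expected = {row[0]: row[3][0] for row in PHANTOM_PLUGS}
        for st in stats:
            assert st.mean_hu == pytest.approx(expected[st.plug_id], abs=2.0), st.plug_id

    def test_determinism_with_fixed_seed(self):
        pat, _ = make_planning_patient(seed=5)
        a, _ = convert_pct_to_pseudo_dect(pat, noise=NoiseModel(rng_seed=11))
        b, _ = convert_pct_to_pseudo_dect(pat, noise=NoiseModel(rng_seed=11))
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert a.domain_tag == "pseudo_dect"

    def test_body_free_input_fails_in_couch_stage(self):
        img = CTImage(voxels=np.full((512, 512), HU_MIN), spacing_mm=(1.3672, 1.3672))
        with pytest.raises(ValueError, match="no body"):
            convert_pct_to_pseudo_dect(img)


class TestRoundTrip:
    def test_interior_within_2hu_and_exterior_exact(self):
        """Forward conversion (noise off) then inversion: soft-tissue
        interior returns within 2 HU; everything outside the 350 mm crop
        window — arms included — is bit-identical."""
        pat, truth = make_planning_patient(seed=0)
        pseudo, record = convert_pct_to_pseudo_dect(
            pat, noise=NoiseModel(target_snr_db=None))
        back = invert_to_planning_ct(pseudo, record)
        r0, c0, win = record.crop_window
        outside = np.ones_like(truth["body"], dtype=bool)
        outside[r0:r0 + win, c0:c0 + win] = False
        np.testing.assert_array_equal(back.voxels[outside], pat.voxels[outside])
        assert truth["arms"].any() and (truth["arms"] & outside).sum() == truth["arms"].sum()
        interior = ndimage.binary_erosion(truth["body"], iterations=3)
        assert np.abs(back.voxels - pat.voxels)[interior].max() <= 2.0
        assert back.domain_tag == "vnc"

    def test_record_geometry_mismatch_rejected(self):
        pat, _ = make_planning_patient(seed=1)
        pseudo, record = convert_pct_to_pseudo_dect(
            pat, noise=NoiseModel(target_snr_db=None))
        other = CTImage(voxels=np.zeros((128, 128)), spacing_mm=(350 / 512, 350 / 512))
        with pytest.raises(ValueError, match="geometry"):
            invert_to_planning_ct(other, record)
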