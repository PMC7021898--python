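"""Rectification and Richardson-Lucy deconvolution."""

import numpy as np
import pytest

from svim.errors import (CalibrationError, ConfigurationError, GeometryError,
                         ParameterError)
from svim.optics import forward_project
from svim.phantoms import make_beads, make_calibration_grid
from svim.reconstruction import (ReconstructionConfig, RectificationParams,
                                 deconvolve, estimate_rectification, rectify,
                                 subtract_background)
from svim.stacks import VolumeStack


class TestEstimateRectification:
    def test_recovers_subpixel_pitch_and_rotation(self):
        img = make_calibration_grid((20, 20), 19.0, 0.5, (420, 420), seed=1)
        p = estimate_rectification(img)
        assert p.pitch_px == pytest.approx(19.0, abs=0.02)
        assert abs(p.rotation_deg) == pytest.approx(0.5, abs=0.05)

    def test_unrotated_grid_recovered_as_zero_rotation(self):
        img = make_calibration_grid((16, 16), 19.0, 0.0, (360, 360), seed=1)
        p = estimate_rectification(img)
        assert abs(p.rotation_deg) <= 0.02

    def test_tolerant_to_one_percent_multiplicative_noise(self):
        img = make_calibration_grid((20, 20), 19.0, 0.5, (420, 420), seed=2,
                                    noise=0.01)
        p = estimate_rectification(img)
        assert p.pitch_px == pytest.approx(19.0, abs=0.02)
        assert abs(p.rotation_deg) == pytest.approx(0.5, abs=0.05)

    def test_too_few_lenslets_rejected(self):
        img = make_calibration_grid((3, 3), 19.0, 0.0, (100, 100), seed=1)
        with pytest.raises(CalibrationError):
            estimate_rectification(img)


class TestRectify:
    def test_identity_on_already_rectified_image(self):
        # grid aligned so output samples coincide with input pixels
        img = make_calibration_grid((21, 21), 15.0, 0.0, (331, 331), seed=1,
                                    center=(165.0, 165.0))
        params = RectificationParams(center=(165.0, 165.0), pitch_px=15.0,
                                     rotation_deg=0.0)
        out = rectify(img, params, 15, out_lenslets=(19, 19))
        h = out.shape[0]
        inner = img[165 - h // 2: 165 + h // 2 + 1, 165 - h // 2: 165 + h // 2 + 1]
        np.testing.assert_allclose(out, inner, rtol=1e-3, atol=1e-9)

    def test_half_pixel_translation_realigned(self):
        img = make_calibration_grid((21, 21), 15.0, 0.0, (331, 331), seed=1,
                                    center=(165.5, 165.5))
        params = RectificationParams(center=(165.5, 165.5), pitch_px=15.0,
                                     rotation_deg=0.0)
        out = rectify(img, params, 15, out_lenslets=(15, 15))
        # every lenslet centre must land on the centre pixel of its 15 px cell
        p = 15
        cells = out.reshape(15, p, 15, p)
        bright = cells.sum(axis=(0, 2))
        peak = np.unravel_index(np.argmax(bright), bright.shape)
        assert peak == ((p - 1) // 2, (p - 1) // 2)
        # sub-pixel: centre of mass of the summed cell within 0.1 px of centre
        yy, xx = np.mgrid[0:p, 0:p]
        com_y = (bright * yy).sum() / bright.sum()
        com_x = (bright * xx).sum() / bright.sum()
        assert com_y == pytest.approx((p - 1) / 2, abs=0.1)
        assert com_x == pytest.approx((p - 1) / 2, abs=0.1)

    def test_total_intensity_conserved_for_interior_content(self):
        # content confined to the inner lenslets, fully covered by the output
        img = make_calibration_grid((13, 13), 19.0, 0.5, (420, 420), seed=1)
        params = estimate_rectification(img)
        out = rectify(img, params, 15)
        assert out.sum() / img.sum() == pytest.approx(1.0, abs=0.005)

    def test_oversized_request_rejected(self):
        img = make_calibration_grid((8, 8), 19.0, 0.0, (180, 180), seed=1)
        params = estimate_rectification(img)
        with pytest.raises(GeometryError):
            rectify(img, params, 15, out_lenslets=(40, 40))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            RectificationParams(center=(0, 0), pitch_px=0.5, rotation_deg=0.0)
        with pytest.raises(ParameterError):
            RectificationParams(center=(0, 0), pitch_px=19.0, rotation_deg=15.0)


class TestReconstructionConfig:
    def test_non_integer_plane_count_rejected(self):
        with pytest.raises(ConfigurationError):
            ReconstructionConfig(z_extent=41.0, z_sampling=2.0)

    def test_z_extent_ceiling_enforced(self):
        with pytest.raises(ConfigurationError):
            ReconstructionConfig(z_extent=500.0, z_sampling=2.0)

    def test_iterations_must_be_positive(self):
        with pytest.raises(ParameterError):
            ReconstructionConfig(z_extent=40.0, z_sampling=2.0, iterations=0)


class TestDeconvolve:
    def test_zero_image_reconstructs_to_zero_after_one_iteration(self, geo_psf_20):
        cfg = ReconstructionConfig(z_extent=80.0, z_sampling=10.0, iterations=1)
        vol = deconvolve(np.zeros(geo_psf_20.sensor_shape), geo_psf_20, cfg)
        assert not vol.values.any()

    def test_objective_monotone_nonincreasing(self, geo_psf_20):
        grid = geo_psf_20.object_grid()
        scene, _ = make_beads(6, 2.0, grid, seed=3)
        lf = forward_project(scene, geo_psf_20)
        cfg = ReconstructionConfig(z_extent=80.0, z_sampling=10.0, iterations=30)
        _, log = deconvolve(lf, geo_psf_20, cfg, return_log=True)
        obj = np.array(log["objective"])
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[:-1]) + 1e-9)

    def test_iterates_nonnegative_and_flux_consistent(self, geo_psf_20):
        grid = geo_psf_20.object_grid()
        ratios = []
        for seed in (3, 4, 5):
            scene, _ = make_beads(5, 2.0, grid, seed=seed)
            lf = forward_project(scene, geo_psf_20)
            cfg = ReconstructionConfig(z_extent=80.0, z_sampling=10.0, iterations=10)
            vol = deconvolve(lf, geo_psf_20, cfg)
            assert vol.values.min() >= 0
            ratios.append(vol.values.sum() / lf.sum())
        assert max(ratios) / min(ratios) < 1.1

    def test_single_bead_round_trip_centroid_within_one_voxel(self, geo_psf_20):
        grid = geo_psf_20.object_grid()
        center = (-10.0, 2.0, -3.0)
        scene, _ = make_beads(1, 1.0, grid, seed=1, centers=[center])
        lf = forward_project(scene, geo_psf_20)
        cfg = ReconstructionConfig(z_extent=80.0, z_sampling=10.0, iterations=30)
        vol = deconvolve(lf, geo_psf_20, cfg)
        v = vol.values
        tot = v.sum()
        zz = vol.z_coords
        yy = grid.coords(1)
        xx = grid.coords(2)
        com = np.array([(v.sum((1, 2)) * zz).sum(), (v.sum((0, 2)) * yy).sum(),
                        (v.sum((0, 1)) * xx).sum()]) / tot
        # centroid of the (peaky) reconstruction near truth; peak voxel exact
        iz, iy, ix = np.unravel_index(np.argmax(v), v.shape)
        assert abs(zz[iz] - center[0]) <= grid.voxel_size[0]
        assert abs(yy[iy] - center[1]) <= grid.voxel_size[1]
        assert abs(xx[ix] - center[2]) <= grid.voxel_size[2]

    def test_deterministic_given_inputs(self, geo_psf_20):
        grid = geo_psf_20.object_grid()
        scene, _ = make_beads(3, 2.0, grid, seed=9)
        lf = forward_project(scene, geo_psf_20)
        cfg = ReconstructionConfig(z_extent=80.0, z_sampling=10.0, iterations=5)
        a = deconvolve(lf, geo_psf_20, cfg).values
        b = deconvolve(lf, geo_psf_20, cfg).values
        np.testing.assert_array_equal(a, b)

    def test_z_extent_beyond_psf_coverage_rejected(self, geo_psf_20):
        cfg = ReconstructionConfig(z_extent=200.0, z_sampling=10.0)
        with pytest.raises(ConfigurationError):
            deconvolve(np.zeros(geo_psf_20.sensor_shape), geo_psf_20, cfg)

    def test_subvolume_reconstruction_selects_matching_planes(self, geo_psf_20):
        cfg = ReconstructionConfig(z_extent=40.0, z_sampling=10.0, z_center=0.0,
                                   iterations=1)
        vol = deconvolve(np.zeros(geo_psf_20.sensor_shape), geo_psf_20, cfg)
        np.testing.assert_allclose(vol.z_coords, [-20, -10, 0, 10, 20])


def test_dark_count_subtraction_clips_at_zero():
    img = np.array([[5.0, 1.0], [0.0, 3.0]])
    out = subtract_background(img, 2.0)
    np.testing.assert_array_equal(out, [[3.0, 0.0], [0.0, 1.0]])
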