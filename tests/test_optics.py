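"""Light-field PSF model and forward/adjoint projector."""

import numpy as np
import pytest

from svim.errors import ConfigurationError, GridMismatchError, ZRangeError
from svim.optics import (OpticalConfig, back_project, compute_lf_psf,
                         forward_project, load_psf, save_psf)
from svim.stacks import VolumeStack


def _config(**kw):
    base = dict(magnification=32.0, numerical_aperture=0.8,
                z_planes=(-10.0, 0.0, 10.0), lenslet_grid=(9, 9))
    base.update(kw)
    return OpticalConfig(**base)


class TestOpticalConfig:
    def test_na_must_be_below_medium_index(self):
        with pytest.raises(ConfigurationError):
            _config(numerical_aperture=1.4)

    def test_pixel_pitch_must_divide_lenslet_pitch(self):
        with pytest.raises(ConfigurationError):
            _config(camera_pixel_pitch=11.0)  # 150/11 = 13.6: >1% residual

    def test_z_planes_strictly_increasing(self):
        with pytest.raises(ConfigurationError):
            _config(z_planes=(0.0, 0.0, 5.0))

    def test_zero_pitch_rejected(self):
        with pytest.raises(ConfigurationError):
            _config(lenslet_pitch=0.0)

    def test_z_outside_validity_range_names_offender(self):
        cfg = _config(z_planes=(-300.0, 0.0, 300.0), psf_model="geometric")
        with pytest.raises(ZRangeError, match="300"):
            compute_lf_psf(cfg)

    def test_object_sampling_follows_magnification(self):
        cfg = _config()
        assert cfg.lenslet_object_pitch == pytest.approx(150.0 / 32.0)
        assert cfg.object_pixel == pytest.approx(150.0 / 32.0 / 5.0)


class TestWavePSF:
    def test_kernels_nonnegative(self, wave_psf_32):
        assert all(k.min() >= 0 for k in wave_psf_32.kernels)

    def test_energy_conserved_across_z(self, wave_psf_32):
        # total sensor energy per unit emitter varies < 5% after normalisation
        e = wave_psf_32.energy_per_z
        assert (e.max() - e.min()) / e.mean() < 0.05

    def test_footprint_radius_nondecreasing_in_abs_z(self, wave_psf_32):
        z = wave_psf_32.z_planes
        r = wave_psf_32.support_radius
        order = np.argsort(np.abs(z), kind="stable")
        # measured footprints grow (to within crop granularity of one lenslet)
        assert r[order][-1] > r[order][0]
        iz0 = int(np.argmin(np.abs(z)))
        for i in range(len(z)):
            if abs(z[i]) > abs(z[iz0]):
                assert r[i] >= r[iz0]

    def test_defocus_footprint_strictly_larger_than_focus(self, wave_psf_32):
        """Brute-force 95%-energy radius at z=+16 um exceeds the in-focus one."""
        def radius95(psf, iz):
            s = psf.config.supersampling
            c = (s - 1) // 2
            K = psf.kernels[iz][c, c].astype(float)
            ay, ax = psf.anchors[iz]
            p = psf.config.pixels_per_lenslet
            yy, xx = np.mgrid[0:K.shape[0], 0:K.shape[1]]
            rr = np.hypot(yy - (ay + (p - 1) / 2), xx - (ax + (p - 1) / 2))
            order = np.argsort(rr.ravel())
            cum = np.cumsum(K.ravel()[order])
            return rr.ravel()[order][np.searchsorted(cum, 0.95 * cum[-1])]

        z = list(wave_psf_32.z_planes)
        assert radius95(wave_psf_32, z.index(16.0)) > radius95(wave_psf_32, z.index(0.0))

    def test_central_lenslet_energy_at_focus(self, wave_psf_32):
        """>= 80% of the energy of an in-focus on-axis emitter lands under its
        own lenslet; cross-checked against a direct Fresnel diffraction
        integral evaluated with an independent quadrature."""
        psf = wave_psf_32
        cfg = psf.config
        s, p = cfg.supersampling, cfg.pixels_per_lenslet
        c = (s - 1) // 2
        iz = list(psf.z_planes).index(0.0)
        K = psf.kernels[iz][c, c]
        ay, ax = psf.anchors[iz]
        frac = K[ay:ay + p, ax:ax + p].sum() / K.sum()
        assert frac >= 0.80

        # independent oracle: direct (matrix, non-FFT) Fresnel integral
        lam, f, pitch = cfg.emission_wavelength, cfg.lenslet_focal_length, cfg.lenslet_pitch
        na_img = cfg.numerical_aperture / cfg.magnification
        n_field, n_sens = 405, 270
        x = (np.arange(n_field) - (n_field - 1) / 2) * (3 * pitch / n_field)
        from scipy.special import j1
        R = np.hypot(x[:, None], x[None, :])
        v = 2 * np.pi / lam * na_img * R
        U = np.where(v < 1e-9, 0.5, j1(np.maximum(v, 1e-9)) / np.maximum(v, 1e-9))
        loc = x - pitch * np.round(x / pitch)
        U = U * np.exp(-1j * np.pi / (lam * f) * loc * loc)[:, None]
        U = U * np.exp(-1j * np.pi / (lam * f) * loc * loc)[None, :]
        u = (np.arange(n_sens) - (n_sens - 1) / 2) * (3 * pitch / n_sens)
        Kf = np.exp(1j * np.pi / (lam * f) * (u[:, None] - x[None, :]) ** 2)
        Us = Kf @ U @ Kf.T
        inten = np.abs(Us) ** 2
        central = (np.abs(u) <= pitch / 2)
        frac_oracle = inten[np.ix_(central, central)].sum() / inten.sum()
        assert frac_oracle >= 0.80
        assert frac == pytest.approx(frac_oracle, abs=0.05)

    def test_lateral_periodicity_by_one_lenslet(self, wave_psf_32):
        """Shifting the emitter by one lenslet shifts the pattern by exactly
        pixels_per_lenslet on the sensor."""
        psf = wave_psf_32
        s, p = psf.config.supersampling, psf.config.pixels_per_lenslet
        grid = psf.object_grid()
        V1 = np.zeros(grid.shape)
        V2 = np.zeros(grid.shape)
        V1[1, 4 * s + 1, 4 * s + 3] = 1.0
        V2[1, 4 * s + 1, 5 * s + 3] = 1.0  # + one lenslet along x
        F1 = forward_project(VolumeStack(V1, grid.voxel_size, grid.z_offset), psf)
        F2 = forward_project(VolumeStack(V2, grid.voxel_size, grid.z_offset), psf)
        np.testing.assert_array_equal(np.roll(F1, p, axis=1)[:, p:], F2[:, p:])


class TestProjector:
    def test_zero_volume_projects_to_zero(self, wave_psf_32):
        grid = wave_psf_32.object_grid()
        out = forward_project(grid.empty(), wave_psf_32)
        assert not out.any()

    def test_unit_voxel_reproduces_stored_kernel(self, wave_psf_32):
        psf = wave_psf_32
        s, p = psf.config.supersampling, psf.config.pixels_per_lenslet
        grid = psf.object_grid()
        iz, ly, lx, pv, pu = 2, 4, 3, 1, 2
        V = np.zeros(grid.shape)
        V[iz, ly * s + pv, lx * s + pu] = 1.0
        F = forward_project(VolumeStack(V, grid.voxel_size, grid.z_offset), psf)
        K = psf.kernels[iz][pv, pu]
        ay, ax = psf.anchors[iz]
        y0, x0 = ly * p - ay, lx * p - ax
        ys, xs = max(0, y0), max(0, x0)
        ye = min(F.shape[0], y0 + K.shape[0])
        xe = min(F.shape[1], x0 + K.shape[1])
        expect = np.zeros_like(F)
        expect[ys:ye, xs:xe] = K[ys - y0:ye - y0, xs - x0:xe - x0]
        np.testing.assert_allclose(F, expect, rtol=0, atol=1e-12)

    def test_two_bead_superposition(self, wave_psf_32):
        psf = wave_psf_32
        grid = psf.object_grid()
        rng = np.random.default_rng(4)
        V1 = np.zeros(grid.shape)
        V2 = np.zeros(grid.shape)
        V1[tuple(rng.integers(0, s) for s in grid.shape)] = 1.0
        V2[tuple(rng.integers(0, s) for s in grid.shape)] = 1.0
        f = lambda v: forward_project(VolumeStack(v, grid.voxel_size, grid.z_offset), psf)
        both = f(V1 + V2)
        np.testing.assert_allclose(both, f(V1) + f(V2), rtol=1e-6, atol=1e-12)

    @pytest.mark.parametrize("psf_name", ["wave_psf_32", "geo_psf_20"])
    def test_adjoint_inner_product_identity(self, psf_name, request):
        """<forward(V), S> == <V, back(S)> on random pairs, both PSF models."""
        psf = request.getfixturevalue(psf_name)
        grid = psf.object_grid()
        rng = np.random.default_rng(0)
        for _ in range(10):
            V = rng.random(grid.shape)
            S = rng.random(psf.sensor_shape)
            FV = forward_project(VolumeStack(V, grid.voxel_size, grid.z_offset), psf)
            BS = back_project(S, psf)
            lhs = float((FV * S).sum())
            rhs = float((V * BS.values).sum())
            assert lhs == pytest.approx(rhs, rel=1e-5)

    def test_backprojected_zero_sensor_is_zero(self, wave_psf_32):
        out = back_project(np.zeros(wave_psf_32.sensor_shape), wave_psf_32)
        assert not out.values.any()

    def test_delta_sensor_backprojects_kernel_values(self, wave_psf_32):
        """A single-pixel sensor image back-projects, at each voxel, the
        kernel value that the voxel would place on that pixel."""
        psf = wave_psf_32
        s, p = psf.config.supersampling, psf.config.pixels_per_lenslet
        S = np.zeros(psf.sensor_shape)
        py, px = 4 * p + 7, 4 * p + 7
        S[py, px] = 1.0
        B = back_project(S, psf).values
        iz, ly, lx, pv, pu = 1, 4, 3, 2, 1
        K = psf.kernels[iz][pv, pu]
        ay, ax = psf.anchors[iz]
        i, j = py - (ly * p - ay), px - (lx * p - ax)
        expect = K[i, j] if (0 <= i < K.shape[0] and 0 <= j < K.shape[1]) else 0.0
        assert B[iz, ly * s + pv, lx * s + pu] == pytest.approx(float(expect), abs=1e-12)

    def test_grid_mismatch_error_names_both_grids(self, wave_psf_32):
        bad = VolumeStack(np.zeros((2, 5, 5)), (1.0, 1.0, 1.0))
        with pytest.raises(GridMismatchError, match="PSF"):
            forward_project(bad, wave_psf_32)
        with pytest.raises(GridMismatchError):
            back_project(np.zeros((7, 7)), wave_psf_32)


def test_psf_hdf5_round_trip(tmp_path, geo_psf_20):
    path = tmp_path / "psf.h5"
    save_psf(geo_psf_20, path)
    loaded = load_psf(path)
    assert loaded.config == geo_psf_20.config
    np.testing.assert_array_equal(loaded.z_planes, geo_psf_20.z_planes)
    np.testing.assert_array_equal(loaded.anchors, geo_psf_20.anchors)
    for a, b in zip(loaded.kernels, geo_psf_20.kernels):
        np.testing.assert_array_equal(a, b)
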