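"""Canned simulation studies used for validation and reproduction.

These functions wire the library modules into the three headline synthetic
experiments: the bead resolution round trip, the illumination-extent
contrast comparison, and the noise-level contrast study.  They are the
single source of truth for the protocols reported by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .metrics import contrast, contrast_z_profile, line_profiles_across_objects, measure_fwhm
from .optics import OpticalConfig, compute_lf_psf, forward_project
from .phantoms import (IlluminationProfile, NoiseSpec, add_poisson_background,
                       make_beads, make_vessels)
from .reconstruction import ReconstructionConfig, deconvolve
from .stacks import VolumeStack

__all__ = [
    "bead_resolution_roundtrip",
    "contrast_vs_illumination_extent",
    "contrast_vs_noise_level",
]


def bead_resolution_roundtrip(magnification: float, numerical_aperture: float,
                              *, n_lenslets: int = 15, bead_z: float = -20.0,
                              z_min: float = -46.0, z_max: float = 2.0,
                              z_sampling: float = 2.0, iterations: int = 30,
                              seed: int = 1) -> dict:
    """Simulate and reconstruct a 0.5 µm bead; measure lateral/axial FWHM.

    The bead sits ``bead_z`` µm off the native focal plane at a seeded random
    sub-lenslet lateral position.  The light-field frame is formed with the
    wave-optics PSF and inverted with ``iterations`` Richardson-Lucy updates
    at ``z_sampling`` µm axial sampling.  FWHMs are measured on line profiles
    through the reconstructed bead centre.

    Note that this noiseless single-bead protocol measures how tightly the
    converged multiplicative updates localise an isolated point — a quantity
    that keeps contracting with iteration count — rather than the two-point
    resolution of the optical system, so its output lies below nominal
    system-resolution figures (see docs/methods.md).
    """
    cfg = OpticalConfig(
        magnification=magnification, numerical_aperture=numerical_aperture,
        z_planes=tuple(np.arange(z_min, z_max + 1e-9, z_sampling)),
        lenslet_grid=(n_lenslets, n_lenslets), supersampling=5)
    psf = compute_lf_psf(cfg)
    grid = psf.object_grid()
    rng = np.random.default_rng(seed)
    # seeded sub-lenslet offset: the bead must not sit on a symmetry point
    off = (rng.random(2) - 0.5) * cfg.lenslet_object_pitch / 2.0
    center = (bead_z, float(off[0]), float(off[1]))
    vol, _ = make_beads(1, 0.5, grid, seed=seed, centers=[center])
    lf = forward_project(vol, psf)
    rec = deconvolve(lf, psf, ReconstructionConfig(
        z_extent=float(z_max - z_min), z_sampling=z_sampling, iterations=iterations))
    R = rec.values
    iz, iy, ix = np.unravel_index(int(np.argmax(R)), R.shape)
    z_um = rec.z_coords[iz]
    yy = grid.coords(1)
    xx = grid.coords(2)
    half = min(10.0, xx[-1] - abs(off).max() - 1.0)
    lines = [((z_um, yy[iy], xx[ix] - half), (z_um, yy[iy], xx[ix] + half)),
             ((z_um, yy[iy] - half, xx[ix]), (z_um, yy[iy] + half, xx[ix]))]
    profs, spac = line_profiles_across_objects(rec, lines, n_samples=161)
    lat = float(np.mean([measure_fwhm(p, s) for p, s in zip(profs, spac)]))
    axial = float(measure_fwhm(R[:, iy, ix], grid.voxel_size[0]))
    return {"lateral_fwhm_um": lat, "axial_fwhm_um": axial,
            "peak_z_um": float(z_um), "bead_center_um": center}


def _vessel_background_scene(psf, seed: int):
    """Vessels inside |z| < 40 µm plus out-of-slab background emitters."""
    grid = psf.object_grid()
    zc = grid.coords(0)
    vol, truth = make_vessels(4, 5.0, grid, seed=seed, orientation="random",
                              curvature=0.5, z_band=(-40.0, 40.0))
    bg, _ = make_beads(250, 8.0, grid, seed=seed + 1, amplitude=0.4)
    bgv = bg.values.copy()
    bgv[np.abs(zc) < 55.0] = 0.0  # background only outside the 100 µm slab
    return VolumeStack(vol.values + bgv, grid.voxel_size, grid.z_offset), truth


def contrast_vs_illumination_extent(*, seed: int = 5, iterations: int = 15) -> dict:
    """Reconstruction contrast z-profiles under SVI-100, SVI-300 and wide-field.

    A fixed vessel phantom inside a 100 µm working slab with autofluorescent
    background emitters outside it; wider illumination excites more of the
    background, degrading per-slice reconstruction contrast.  Uses the fast
    geometric PSF on a tall (±250 µm) simulation volume at 20x/0.5 NA.
    """
    cfg = OpticalConfig(magnification=20.0, numerical_aperture=0.5,
                        z_planes=tuple(np.arange(-250.0, 251.0, 10.0)),
                        lenslet_grid=(9, 9), supersampling=3,
                        psf_model="geometric")
    psf = compute_lf_psf(cfg)
    scene, _ = _vessel_background_scene(psf, seed)
    rcfg = ReconstructionConfig(z_extent=80.0, z_sampling=10.0, z_center=0.0,
                                iterations=iterations)
    from .phantoms import apply_illumination
    out = {}
    for name, prof in [("svi100", IlluminationProfile("selective", 0.0, 100.0, 5.0)),
                       ("svi300", IlluminationProfile("selective", 0.0, 300.0, 5.0)),
                       ("widefield", IlluminationProfile("wide-field"))]:
        lit = apply_illumination(scene, prof)
        lf = forward_project(lit, psf)
        rec = deconvolve(lf, psf, rcfg)
        out[name] = contrast_z_profile(rec)
    return out


def contrast_vs_noise_level(lambdas=(50.0, 500.0, 8400.0), *, seed: int = 5,
                            iterations: int = 30) -> dict:
    """Reconstruction contrast after scale-then-Poisson corruption at each λ.

    A dense scene (vessels over diffuse tissue) inside a 100 µm slab; the raw
    light-field frame is rescaled so its mean photon count equals λ, Poisson
    noise applied per pixel, and the reconstruction contrast measured.  At
    low λ the shot-noise speckle reprojected into the volume inflates the
    normalised standard deviation, so contrast decreases as λ grows toward
    the noiseless limit.
    """
    cfg = OpticalConfig(magnification=20.0, numerical_aperture=0.5,
                        z_planes=tuple(np.arange(-40.0, 41.0, 10.0)),
                        lenslet_grid=(9, 9), supersampling=3,
                        psf_model="geometric")
    psf = compute_lf_psf(cfg)
    grid = psf.object_grid()
    vol, _ = make_vessels(4, 5.0, grid, seed=seed, orientation="random",
                          curvature=0.5)
    scene = VolumeStack(vol.values + 0.3, grid.voxel_size, grid.z_offset)
    from .phantoms import apply_illumination
    lit = apply_illumination(scene, IlluminationProfile("selective", 0.0, 100.0, 5.0))
    lf = forward_project(lit, psf)
    rcfg = ReconstructionConfig(z_extent=80.0, z_sampling=10.0, z_center=0.0,
                                iterations=iterations)
    results = {"lambda": [], "contrast": [], "noisy_mean": []}
    for lam in lambdas:
        noisy = add_poisson_background(lf, NoiseSpec(lam, seed=seed + 6))
        rec = deconvolve(noisy, psf, rcfg)
        results["lambda"].append(float(lam))
        results["contrast"].append(contrast(rec.values))
        results["noisy_mean"].append(float(noisy.mean()))
    return results
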