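"""Light-field optics: PSF computation and linear forward/adjoint projection.

The imaging path is a fluorescence microscope (objective + tube lens) with a
micro-lens array (MLA) at the image plane and the camera at the MLA focal
plane.  A point emitter at depth z produces a characteristic multi-lenslet
pattern on the sensor; the set of these patterns, indexed by z-plane and by
the emitter's sub-lenslet lateral phase, is the kernel of the linear
image-formation model used for simulation and reconstruction.

Two PSF models are provided:

``wave``
    Scalar Debye theory.  The amplitude PSF of the objective (with paraxial
    defocus) is evaluated at the native image plane, multiplied by the
    quadratic phase of the square-aperture lenslet array, and Fresnel
    propagated one lenslet focal length to the sensor.  This is the model to
    use for quantitative resolution work.

``geometric``
    A fast ray-optics approximation (Gaussian spots per lenslet, weights from
    the defocus blur disc).  Orders of magnitude faster; intended for smoke
    tests and qualitative contrast studies, not for resolution claims.

Coordinates: z = 0 µm is the native focal plane, positive z toward the
detection objective; lateral origin at the centre of the central lenslet;
array order (z, y, x); all physical units µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit
from numba.typed import List as _NumbaList
from scipy.special import j0, roots_legendre

from .errors import ConfigurationError, GridMismatchError, ZRangeError
from .stacks import GridSpec, VolumeStack

__all__ = [
    "OpticalConfig",
    "LightFieldPSF",
    "compute_lf_psf",
    "forward_project",
    "back_project",
    "save_psf",
    "load_psf",
]

PSF_FORMAT_VERSION = 1


@dataclass(frozen=True)
class OpticalConfig:
    """Full description of the light-field imaging path, in physical units.

    Parameters
    ----------
    magnification : float
        Total magnification objective × tube lens.
    numerical_aperture : float
        Detection NA; must be smaller than ``medium_refractive_index``.
    z_planes : tuple of float
        Strictly increasing object-space z positions (µm) at which PSF
        kernels are computed; z = 0 is the native focal plane.
    emission_wavelength : float
        Fluorescence emission wavelength in µm (monochromatic model).
    medium_refractive_index : float
        Refractive index of the sample medium (water by default).
    lenslet_pitch : float
        MLA pitch at the image plane, µm.
    lenslet_focal_length : float
        MLA focal length, µm; the camera sits at this distance.
    camera_pixel_pitch : float
        Physical camera pixel size, µm.  ``round(pitch / pixel)`` must land
        within 1% of an integer number of pixels per lenslet.
    lenslet_grid : (int, int)
        Lenslet counts ``(n_v, n_u)`` along (y, x).
    supersampling : int
        Odd number of reconstructed object-space samples per lenslet and
        lateral axis (sub-lenslet phases).
    psf_model : {"wave", "geometric"}
    oversampling : int
        Odd number of wave-optics field samples per camera pixel.
    max_defocus : float
        Documented validity limit on the defocus magnitude of the PSF model, µm.
    """

    magnification: float
    numerical_aperture: float
    z_planes: tuple[float, ...]
    emission_wavelength: float = 0.52
    medium_refractive_index: float = 1.33
    lenslet_pitch: float = 150.0
    lenslet_focal_length: float = 3000.0
    camera_pixel_pitch: float = 10.0
    lenslet_grid: tuple[int, int] = (15, 15)
    supersampling: int = 5
    psf_model: str = "wave"
    oversampling: int = 3
    max_defocus: float = 250.0

    def __post_init__(self) -> None:
        if self.numerical_aperture <= 0 or self.numerical_aperture >= self.medium_refractive_index:
            raise ConfigurationError(
                f"numerical aperture ({self.numerical_aperture}) must be in "
                f"(0, n={self.medium_refractive_index})"
            )
        for name in ("magnification", "emission_wavelength", "lenslet_pitch",
                     "lenslet_focal_length", "camera_pixel_pitch", "max_defocus"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        ppl = round(self.lenslet_pitch / self.camera_pixel_pitch)
        if ppl < 1:
            raise ConfigurationError("camera pixel pitch larger than lenslet pitch")
        residual = abs(self.lenslet_pitch - ppl * self.camera_pixel_pitch)
        if residual >= 0.01 * self.lenslet_pitch:
            raise ConfigurationError(
                f"lenslet pitch {self.lenslet_pitch} µm is not an integer number of "
                f"camera pixels ({self.camera_pixel_pitch} µm) within 1%"
            )
        z = np.asarray(self.z_planes, dtype=float)
        if z.ndim != 1 or z.size == 0:
            raise ConfigurationError("z_planes must be a non-empty 1D sequence")
        if z.size > 1 and not np.all(np.diff(z) > 0):
            raise ConfigurationError("z_planes must be strictly increasing")
        object.__setattr__(self, "z_planes", tuple(float(v) for v in z))
        if self.supersampling < 1 or self.supersampling % 2 == 0:
            raise ConfigurationError("supersampling must be a positive odd integer")
        if self.oversampling < 1 or self.oversampling % 2 == 0:
            raise ConfigurationError("oversampling must be a positive odd integer")
        if self.psf_model not in ("wave", "geometric"):
            raise ConfigurationError(f"unknown psf_model {self.psf_model!r}")
        if len(self.lenslet_grid) != 2 or any(int(n) < 1 for n in self.lenslet_grid):
            raise ConfigurationError(f"lenslet_grid must be two positive ints, got {self.lenslet_grid}")

    @property
    def pixels_per_lenslet(self) -> int:
        return round(self.lenslet_pitch / self.camera_pixel_pitch)

    @property
    def lenslet_object_pitch(self) -> float:
        """Object-space lateral extent of one lenslet, µm."""
        return self.lenslet_pitch / self.magnification

    @property
    def object_pixel(self) -> float:
        """Object-space lateral sampling of the reconstruction grid, µm."""
        return self.lenslet_object_pitch / self.supersampling

    @property
    def sin_alpha(self) -> float:
        return self.numerical_aperture / self.medium_refractive_index

    @property
    def tan_alpha(self) -> float:
        s = self.sin_alpha
        return s / np.sqrt(1.0 - s * s)


# ---------------------------------------------------------------------------
# wave-optics model
# ---------------------------------------------------------------------------

_DEBYE_NODES = 200


def _debye_radial(r_obj: np.ndarray, z: float, cfg: OpticalConfig) -> np.ndarray:
    """Scalar Debye amplitude PSF h(r; z) of the objective, paraxial defocus.

    ``r_obj`` are object-space radial distances in µm.  Normalisation is
    arbitrary (kernels are normalised globally later).
    """
    k = 2.0 * np.pi / cfg.emission_wavelength
    v = k * cfg.numerical_aperture * np.asarray(r_obj, dtype=float)
    u = k * (cfg.numerical_aperture ** 2 / cfg.medium_refractive_index) * z
    rho, w = roots_legendre(_DEBYE_NODES)
    rho = 0.5 * (rho + 1.0)  # map [-1, 1] -> [0, 1]
    w = 0.5 * w
    phase = np.exp(0.5j * u * rho * rho) * rho * w
    return j0(np.outer(v, rho)) @ phase


def _window_lenslets(cfg: OpticalConfig, z: float) -> int:
    """Odd lenslet count of the simulation window for depth z.

    The geometric model spreads energy in Gaussian tails beyond the sharp
    ray-optics blur circle, so its window carries an extra 30% margin.
    """
    r_img = abs(z) * cfg.tan_alpha * cfg.magnification
    if cfg.psf_model == "geometric":
        r_img *= 1.3
    radius = int(np.ceil(r_img / cfg.lenslet_pitch)) + 3
    return 2 * radius + 1


def _wave_base_kernel(cfg: OpticalConfig, z: float, ey: float, ex: float) -> np.ndarray:
    """Sensor-pixel intensity pattern of a unit emitter at (z, ey, ex).

    (ey, ex) are object-space offsets from the centre of the emitter's
    lenslet.  Returns an array of shape (W*p, W*p) where W is the odd
    window size in lenslets, centred on the emitter's lenslet.
    """
    p = cfg.pixels_per_lenslet
    osamp = cfg.oversampling
    W = _window_lenslets(cfg, z)
    N = W * p * osamp
    pitch = cfg.lenslet_pitch
    delta = pitch / (p * osamp)
    lam = cfg.emission_wavelength
    f = cfg.lenslet_focal_length
    M = cfg.magnification

    c = (np.arange(N) - (N - 1) / 2.0) * delta
    qy, qx = M * ey, M * ex

    # field at the native image plane, evaluated via a radial profile
    rmax = np.hypot(c[-1] - min(qy, qx, 0.0), c[-1]) / M + 2.0 * delta / M
    r_grid = np.linspace(0.0, rmax, max(512, int(4 * rmax * M / delta)))
    prof = _debye_radial(r_grid, z, cfg)
    r2 = (c[:, None] - qy) ** 2 + (c[None, :] - qx) ** 2
    r = np.sqrt(r2, out=r2) / M
    U = (np.interp(r, r_grid, prof.real) + 1j * np.interp(r, r_grid, prof.imag))

    # lenslet-array quadratic phase (square lenslets, unit fill factor)
    loc = c - pitch * np.round(c / pitch)
    k0 = 2.0 * np.pi / lam
    ph = np.exp(-0.5j * k0 / f * loc * loc)
    U *= ph[:, None]
    U *= ph[None, :]

    # Fresnel propagation (transfer-function method) to the sensor
    fx = np.fft.fftfreq(N, delta)
    h1 = np.exp(-1j * np.pi * lam * f * fx * fx)
    A = np.fft.fft2(U)
    A *= h1[:, None]
    A *= h1[None, :]
    Us = np.fft.ifft2(A)

    inten = np.abs(Us) ** 2
    return inten.reshape(W * p, osamp, W * p, osamp).sum(axis=(1, 3))


def _expand_phases(cfg: OpticalConfig, z: float) -> np.ndarray:
    """All (s × s) sub-lenslet phase kernels at one z, shape (s, s, H, W).

    Mirror and transpose symmetry of the optical train (square lenslets,
    isotropic propagation, odd pixel counts) reduces the s² computations to
    the unique set {0 <= a <= b <= (s-1)/2}.
    """
    s = cfg.supersampling
    cph = (s - 1) // 2
    dx = cfg.object_pixel
    base: dict[tuple[int, int], np.ndarray] = {}
    for a in range(cph + 1):
        for b in range(a, cph + 1):
            base[(a, b)] = _wave_base_kernel(cfg, z, a * dx, b * dx)
    H = base[(0, 0)].shape[0]
    out = np.empty((s, s, H, H), dtype=np.float64)
    for pv in range(s):
        for pu in range(s):
            a, b = pv - cph, pu - cph
            aa, bb = abs(a), abs(b)
            K = base[(aa, bb)] if aa <= bb else base[(bb, aa)].T
            if a < 0:
                K = K[::-1, :]
            if b < 0:
                K = K[:, ::-1]
            out[pv, pu] = K
    return out


# ---------------------------------------------------------------------------
# geometric (ray-optics) fallback model
# ---------------------------------------------------------------------------

def _norm_cdf(x: np.ndarray) -> np.ndarray:
    from scipy.special import erf
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def _geometric_axis(cfg: OpticalConfig, z: float, e: float, W: int) -> np.ndarray:
    """Per-lenslet 1D sensor profiles along one axis; shape (W, W*p)."""
    p = cfg.pixels_per_lenslet
    pitch = cfg.lenslet_pitch
    f = cfg.lenslet_focal_length
    M = cfg.magnification
    lam = cfg.emission_wavelength
    na_img = cfg.numerical_aperture / M
    q = M * e
    zeta = M * M * z / cfg.medium_refractive_index  # image-side defocus
    r_blur = abs(zeta) * na_img
    sigma_airy = 0.21 * lam / na_img
    sig_m = np.sqrt((r_blur / 2.0) ** 2 + sigma_airy ** 2)
    # effective source extent at the MLA plane: cover the Gaussian tails of
    # the blur model, not just the hard ray-optics disc
    r_tot = max(r_blur, 2.5 * sig_m) + sigma_airy

    pix = cfg.lenslet_pitch / p
    g = (np.arange(W * p) - (W * p - 1) / 2.0) * pix  # pixel centres, µm
    centers = (np.arange(W) - (W - 1) / 2.0) * pitch
    sigma_d = 0.42 * lam * f / pitch

    out = np.zeros((W, W * p))
    for i, L in enumerate(centers):
        # energy fraction through this lenslet (Gaussian blur model)
        wgt = _norm_cdf(np.array([(L + pitch / 2 - q) / sig_m]))[0] - \
              _norm_cdf(np.array([(L - pitch / 2 - q) / sig_m]))[0]
        if wgt < 1e-8:
            continue
        e1 = max(L - pitch / 2, q - r_tot)
        e2 = min(L + pitch / 2, q + r_tot)
        if e2 <= e1:
            continue
        if abs(zeta) < 1e-9:
            c_s, half = q, f * na_img
        else:
            s1 = e1 + f * (e1 - q) / zeta
            s2 = e2 + f * (e2 - q) / zeta
            c_s, half = 0.5 * (s1 + s2), 0.5 * abs(s2 - s1)
        sigma = np.hypot(half / 1.75, sigma_d)
        prof = _norm_cdf((g + pix / 2 - c_s) / sigma) - _norm_cdf((g - pix / 2 - c_s) / sigma)
        out[i] = wgt * prof
    return out


def _geometric_kernel(cfg: OpticalConfig, z: float, ey: float, ex: float) -> np.ndarray:
    # per-lenslet spots are separable in (y, x), so the double lenslet sum
    # collapses to a rank-1 outer product of the per-axis profile sums
    W = _window_lenslets(cfg, z)
    ay = _geometric_axis(cfg, z, ey, W).sum(axis=0)
    ax = _geometric_axis(cfg, z, ex, W).sum(axis=0)
    return np.outer(ay, ax)


# ---------------------------------------------------------------------------
# PSF container
# ---------------------------------------------------------------------------

@dataclass
class LightFieldPSF:
    """Discretised light-field PSF: per-(z, phase) sensor kernels.

    ``kernels[iz]`` has shape (s, s, kh, kw): the sensor response of a unit
    emitter at ``z_planes[iz]`` with sub-lenslet phase (pv, pu), as float32.
    ``anchors[iz] = (ay, ax)`` is the kernel pixel that coincides with the
    first (top-left) sensor pixel of the emitter's own lenslet.  Kernels are
    normalised so the mean total sensor energy per unit emitter is 1.
    """

    config: OpticalConfig
    z_planes: np.ndarray
    kernels: list[np.ndarray]
    anchors: np.ndarray
    energy_per_z: np.ndarray
    _packed: object = field(default=None, repr=False, compare=False)

    @property
    def support_radius(self) -> np.ndarray:
        """Per-z kernel footprint radius in lenslets (after truncation)."""
        p = self.config.pixels_per_lenslet
        return np.array([(max(k.shape[2], k.shape[3]) / p - 1.0) / 2.0 for k in self.kernels])

    def object_grid(self) -> GridSpec:
        """Reconstruction grid matching this PSF (requires uniform z spacing)."""
        z = self.z_planes
        if z.size > 1:
            dz = np.diff(z)
            if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
                raise ConfigurationError("object_grid requires uniformly spaced z_planes")
            dz0 = float(dz[0])
        else:
            dz0 = 1.0
        cfg = self.config
        n_v, n_u = cfg.lenslet_grid
        s = cfg.supersampling
        return GridSpec(
            shape=(z.size, n_v * s, n_u * s),
            voxel_size=(dz0, cfg.object_pixel, cfg.object_pixel),
            z_offset=float(z[0]),
        )

    @property
    def sensor_shape(self) -> tuple[int, int]:
        n_v, n_u = self.config.lenslet_grid
        p = self.config.pixels_per_lenslet
        return (n_v * p, n_u * p)

    def subset(self, z_indices: np.ndarray) -> "LightFieldPSF":
        """A new PSF restricted to a subset of z-planes."""
        idx = np.asarray(z_indices)
        return LightFieldPSF(
            config=self.config,
            z_planes=self.z_planes[idx],
            kernels=[self.kernels[i] for i in idx],
            anchors=self.anchors[idx],
            energy_per_z=self.energy_per_z[idx],
        )

    def packed(self):
        if self._packed is None:
            lst = _NumbaList()
            for k in self.kernels:
                lst.append(np.ascontiguousarray(k, dtype=np.float32))
            self._packed = lst
        return self._packed


def compute_lf_psf(config: OpticalConfig) -> LightFieldPSF:
    """Compute the light-field PSF for every (z-plane, sub-lenslet phase).

    Deterministic for a fixed config.  Raises :class:`ZRangeError` for
    z-planes beyond ``config.max_defocus`` and :class:`ConfigurationError`
    for non-physical optics.
    """
    for z in config.z_planes:
        if abs(z) > config.max_defocus:
            raise ZRangeError(
                f"z-plane {z} µm outside the PSF validity range "
                f"(|z| <= {config.max_defocus} µm)"
            )
    s = config.supersampling
    cph = (s - 1) // 2
    dx = config.object_pixel
    kernels: list[np.ndarray] = []
    anchors = []
    p = config.pixels_per_lenslet
    for z in config.z_planes:
        if config.psf_model == "wave":
            K4 = _expand_phases(config, z)
        else:
            W = _window_lenslets(config, z)
            K4 = np.empty((s, s, W * p, W * p))
            for pv in range(s):
                for pu in range(s):
                    K4[pv, pu] = _geometric_kernel(config, z, (pv - cph) * dx, (pu - cph) * dx)
        anchor = ((K4.shape[2] // p - 1) // 2) * p
        K4, ay, ax = _truncate(K4, anchor, anchor)
        kernels.append(K4.astype(np.float32))
        anchors.append((ay, ax))

    energies = np.array([[k[i, j].sum() for i in range(s) for j in range(s)] for k in kernels])
    norm = energies.mean()
    if norm <= 0:
        raise ConfigurationError("computed PSF has zero energy")
    kernels = [(k / norm).astype(np.float32) for k in kernels]
    energy_per_z = energies.mean(axis=1) / norm
    rel_spread = (energy_per_z.max() - energy_per_z.min()) / energy_per_z.mean()
    if rel_spread > 0.05:
        warnings.warn(
            f"PSF energy varies by {100 * rel_spread:.1f}% across z; "
            "the simulation window may be too small", stacklevel=2)
    return LightFieldPSF(
        config=config,
        z_planes=np.asarray(config.z_planes, dtype=float),
        kernels=kernels,
        anchors=np.asarray(anchors, dtype=np.int64),
        energy_per_z=energy_per_z,
    )


def _truncate(K4: np.ndarray, ay: int, ax: int, keep: float = 0.999):
    """Trim outer rows/cols while every phase keeps >= ``keep`` of its energy."""
    totals = K4.sum(axis=(2, 3))
    totals[totals == 0] = 1.0
    y0, y1 = 0, K4.shape[2]
    x0, x1 = 0, K4.shape[3]
    lost = np.zeros_like(totals)

    def loss(sl_y, sl_x):
        return K4[:, :, sl_y, sl_x].sum(axis=(2, 3)) / totals

    while True:
        candidates = []
        if y1 - y0 > 1:
            candidates.append(("top", loss(slice(y0, y0 + 1), slice(x0, x1))))
            candidates.append(("bottom", loss(slice(y1 - 1, y1), slice(x0, x1))))
        if x1 - x0 > 1:
            candidates.append(("left", loss(slice(y0, y1), slice(x0, x0 + 1))))
            candidates.append(("right", loss(slice(y0, y1), slice(x1 - 1, x1))))
        best = None
        for side, frac in candidates:
            worst = (lost + frac).max()
            if worst < 1.0 - keep and (best is None or worst < best[1]):
                best = (side, worst, frac)
        if best is None:
            break
        side, _, frac = best
        lost = lost + frac
        if side == "top":
            y0 += 1
        elif side == "bottom":
            y1 -= 1
        elif side == "left":
            x0 += 1
        else:
            x1 -= 1
    return np.ascontiguousarray(K4[:, :, y0:y1, x0:x1]), ay - y0, ax - x0


# ---------------------------------------------------------------------------
# forward / adjoint projection (numba inner loops)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fwd_loop(vol, kerns, anchors, s, p, out):  # pragma: no cover - jitted
    nz, ny, nx = vol.shape
    n_v = ny // s
    n_u = nx // s
    H, Wd = out.shape
    for iz in range(nz):
        K4 = kerns[iz]
        kh = K4.shape[2]
        kw = K4.shape[3]
        ay = anchors[iz, 0]
        ax = anchors[iz, 1]
        for pv in range(s):
            for pu in range(s):
                K = K4[pv, pu]
                for ly in range(n_v):
                    y0 = ly * p - ay
                    ks_y = 0 if y0 >= 0 else -y0
                    ke_y = kh if y0 + kh <= H else H - y0
                    if ke_y <= ks_y:
                        continue
                    vy = ly * s + pv
                    for lx in range(n_u):
                        v = vol[iz, vy, lx * s + pu]
                        if v == 0.0:
                            continue
                        x0 = lx * p - ax
                        ks_x = 0 if x0 >= 0 else -x0
                        ke_x = kw if x0 + kw <= Wd else Wd - x0
                        if ke_x <= ks_x:
                            continue
                        for i in range(ks_y, ke_y):
                            oy = y0 + i
                            for j in range(ks_x, ke_x):
                                out[oy, x0 + j] += v * K[i, j]


@njit(cache=True)
def _adj_loop(sensor, kerns, anchors, s, p, out):  # pragma: no cover - jitted
    nz, ny, nx = out.shape
    n_v = ny // s
    n_u = nx // s
    H, Wd = sensor.shape
    for iz in range(nz):
        K4 = kerns[iz]
        kh = K4.shape[2]
        kw = K4.shape[3]
        ay = anchors[iz, 0]
        ax = anchors[iz, 1]
        for pv in range(s):
            for pu in range(s):
                K = K4[pv, pu]
                for ly in range(n_v):
                    y0 = ly * p - ay
                    ks_y = 0 if y0 >= 0 else -y0
                    ke_y = kh if y0 + kh <= H else H - y0
                    if ke_y <= ks_y:
                        continue
                    vy = ly * s + pv
                    for lx in range(n_u):
                        x0 = lx * p - ax
                        ks_x = 0 if x0 >= 0 else -x0
                        ke_x = kw if x0 + kw <= Wd else Wd - x0
                        if ke_x <= ks_x:
                            continue
                        acc = 0.0
                        for i in range(ks_y, ke_y):
                            sy = y0 + i
                            for j in range(ks_x, ke_x):
                                acc += sensor[sy, x0 + j] * K[i, j]
                        out[iz, vy, lx * s + pu] = acc


def _check_volume(volume: VolumeStack, psf: LightFieldPSF) -> None:
    grid = psf.object_grid()
    if volume.values.shape != grid.shape:
        raise GridMismatchError(
            f"volume grid {volume.values.shape} does not match the PSF object "
            f"grid {grid.shape} (lenslet_grid={psf.config.lenslet_grid}, "
            f"supersampling={psf.config.supersampling}, nz={psf.z_planes.size})"
        )
    if not np.allclose(volume.voxel_size[1:], grid.voxel_size[1:], rtol=1e-6):
        raise GridMismatchError(
            f"volume lateral voxel size {volume.voxel_size[1:]} µm does not match "
            f"the PSF object pixel {grid.voxel_size[1]:.4f} µm"
        )
    if not np.allclose(volume.z_coords, psf.z_planes, atol=1e-6):
        raise GridMismatchError(
            f"volume z grid [{volume.z_coords[0]:.2f}..{volume.z_coords[-1]:.2f}] µm "
            f"does not match PSF z_planes [{psf.z_planes[0]:.2f}..{psf.z_planes[-1]:.2f}] µm"
        )


def _forward_raw(vol: np.ndarray, psf: LightFieldPSF) -> np.ndarray:
    out = np.zeros(psf.sensor_shape, dtype=np.float64)
    _fwd_loop(np.ascontiguousarray(vol, dtype=np.float64), psf.packed(), psf.anchors,
              psf.config.supersampling, psf.config.pixels_per_lenslet, out)
    return out


def _adjoint_raw(sensor: np.ndarray, psf: LightFieldPSF) -> np.ndarray:
    grid = psf.object_grid()
    out = np.zeros(grid.shape, dtype=np.float64)
    _adj_loop(np.ascontiguousarray(sensor, dtype=np.float64), psf.packed(), psf.anchors,
              psf.config.supersampling, psf.config.pixels_per_lenslet, out)
    return out


def forward_project(volume: VolumeStack, psf: LightFieldPSF) -> np.ndarray:
    """Project an object volume to the 2D sensor (linear image formation).

    The volume must live on ``psf.object_grid()``.  Returns the sensor image
    as a float64 array of shape ``psf.sensor_shape``.
    """
    _check_volume(volume, psf)
    return _forward_raw(volume.values, psf)


def back_project(sensor_image: np.ndarray, psf: LightFieldPSF) -> VolumeStack:
    """Exact adjoint of :func:`forward_project`."""
    sensor_image = np.asarray(sensor_image)
    if sensor_image.shape != psf.sensor_shape:
        raise GridMismatchError(
            f"sensor image shape {sensor_image.shape} does not match the PSF "
            f"sensor shape {psf.sensor_shape}"
        )
    grid = psf.object_grid()
    return VolumeStack(_adjoint_raw(sensor_image, psf), grid.voxel_size, grid.z_offset)


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_psf(psf: LightFieldPSF, path) -> None:
    """Persist a PSF to HDF5 (kernels per z, full optical configuration)."""
    cfg = psf.config
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = PSF_FORMAT_VERSION
        for name in ("magnification", "numerical_aperture", "emission_wavelength",
                     "medium_refractive_index", "lenslet_pitch", "lenslet_focal_length",
                     "camera_pixel_pitch", "supersampling", "oversampling", "max_defocus"):
            f.attrs[name] = getattr(cfg, name)
        f.attrs["psf_model"] = cfg.psf_model
        f.attrs["lenslet_grid"] = cfg.lenslet_grid
        f.attrs["assumed_defaults"] = (
            "emission_wavelength, camera_pixel_pitch and medium_refractive_index "
            "are model assumptions, not measured instrument values"
        )
        f.create_dataset("z_planes", data=psf.z_planes)
        f.create_dataset("anchors", data=psf.anchors)
        f.create_dataset("energy_per_z", data=psf.energy_per_z)
        g = f.create_group("kernels")
        for i, k in enumerate(psf.kernels):
            g.create_dataset(f"z{i:04d}", data=k, compression="gzip", compression_opts=4)


def load_psf(path) -> LightFieldPSF:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", 0))
        if version > PSF_FORMAT_VERSION:
            raise ConfigurationError(f"unsupported PSF file version {version}")
        z = np.asarray(f["z_planes"])
        cfg = OpticalConfig(
            magnification=float(f.attrs["magnification"]),
            numerical_aperture=float(f.attrs["numerical_aperture"]),
            z_planes=tuple(z),
            emission_wavelength=float(f.attrs["emission_wavelength"]),
            medium_refractive_index=float(f.attrs["medium_refractive_index"]),
            lenslet_pitch=float(f.attrs["lenslet_pitch"]),
            lenslet_focal_length=float(f.attrs["lenslet_focal_length"]),
            camera_pixel_pitch=float(f.attrs["camera_pixel_pitch"]),
            lenslet_grid=tuple(int(v) for v in f.attrs["lenslet_grid"]),
            supersampling=int(f.attrs["supersampling"]),
            psf_model=str(f.attrs["psf_model"]),
            oversampling=int(f.attrs["oversampling"]),
            max_defocus=float(f.attrs["max_defocus"]),
        )
        kernels = [np.asarray(f["kernels"][f"z{i:04d}"]) for i in range(z.size)]
        return LightFieldPSF(
            config=cfg,
            z_planes=z,
            kernels=kernels,
            anchors=np.asarray(f["anchors"]),
            energy_per_z=np.asarray(f["energy_per_z"]),
        )
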