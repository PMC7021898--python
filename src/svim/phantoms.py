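"""Synthetic fluorophore phantoms with known ground truth.

Generators for the test objects used throughout the toolkit: sub-diffractive
beads (resolution), vessel-like tubes (contrast/FWHM), blinking nuclei
(calcium-imaging activity) and flowing particles (3D tracking), plus the
selective-volume illumination model and the scale-then-Poisson background
noise procedure.

Every generator is a pure function of its parameters and seed: the same call
returns bit-identical output.  Geometry and noise draw from independent
substreams of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .stacks import GridSpec, TimeSeriesStack, VolumeStack

__all__ = [
    "GroundTruth",
    "IlluminationProfile",
    "NoiseSpec",
    "make_beads",
    "make_vessels",
    "make_nuclei_timeseries",
    "make_flowing_particles",
    "make_calibration_grid",
    "apply_illumination",
    "add_poisson_background",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class GroundTruth:
    """Planted object parameters recorded by the generators.

    ``centers`` are (n, 3) positions in µm, (z, y, x) order.  Time-dependent
    generators fill ``traces`` (n, T), ``spike_times`` (list of arrays, s) or
    ``trajectories`` (n, T, 3).
    """

    centers: np.ndarray
    sizes: np.ndarray | None = None
    traces: np.ndarray | None = None
    spike_times: list | None = None
    trajectories: np.ndarray | None = None
    active: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.centers)


def _rng(seed: int, stream: str) -> np.random.Generator:
    # stable named substreams: crc32 is deterministic across processes
    import zlib
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())]))


def _render_blob(values: np.ndarray, grid: GridSpec, center, sigmas) -> None:
    """Add a unit-peak anisotropic Gaussian blob in place."""
    coords = [grid.coords(a) for a in range(3)]
    sl = []
    axes = []
    for a in range(3):
        lo = np.searchsorted(coords[a], center[a] - 4 * sigmas[a] - grid.voxel_size[a])
        hi = np.searchsorted(coords[a], center[a] + 4 * sigmas[a] + grid.voxel_size[a])
        lo, hi = max(lo, 0), min(hi, grid.shape[a])
        if hi <= lo:
            return
        sl.append(slice(lo, hi))
        axes.append(np.exp(-0.5 * ((coords[a][lo:hi] - center[a]) / sigmas[a]) ** 2))
    values[tuple(sl)] += axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def make_beads(n: int, bead_diameter: float, grid: GridSpec, seed: int,
               *, amplitude: float = 1.0, margin: float | None = None,
               centers: np.ndarray | None = None) -> tuple[VolumeStack, GroundTruth]:
    """Random sub-resolvable beads rendered as Gaussian blobs of FWHM = diameter.

    Positions are uniform within the grid, inset by ``margin`` (default one
    bead diameter plus one voxel) from every face.  Pass explicit ``centers``
    (µm, (z, y, x)) to place beads deterministically.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if bead_diameter <= 0:
        raise ParameterError("bead_diameter must be positive")
    sig = np.array([bead_diameter / _FWHM] * 3)
    if margin is None:
        margin = bead_diameter + max(grid.voxel_size)
    bounds = grid.bounds()
    if centers is None:
        lo = np.array([b[0] + margin for b in bounds])
        hi = np.array([b[1] - margin for b in bounds])
        if np.any(hi <= lo):
            raise ParameterError(
                f"grid extent {grid.extent} µm too small for beads of diameter "
                f"{bead_diameter} µm with margin {margin} µm")
        rng = _rng(seed, "beads")
        centers = lo + (hi - lo) * rng.random((n, 3))
    else:
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
    vol = grid.empty()
    for c in centers:
        _render_blob(vol.values, grid, c, sig)
    vol.values *= amplitude
    truth = GroundTruth(centers=centers, sizes=np.full(len(centers), bead_diameter))
    return vol, truth


def _smooth_curve(rng: np.random.Generator, bounds, n_pts: int, curvature: float) -> np.ndarray:
    """A smooth 3D polyline crossing the volume, mostly along y."""
    from scipy.interpolate import CubicSpline
    (z0, z1), (y0, y1), (x0, x1) = bounds
    t = np.linspace(0.0, 1.0, 5)
    ctrl = np.empty((5, 3))
    ctrl[:, 1] = y0 + (y1 - y0) * t                      # runs along y
    ctrl[:, 0] = rng.uniform(z0, z1) + curvature * (z1 - z0) * rng.standard_normal(5) * 0.1
    ctrl[:, 2] = rng.uniform(x0, x1) + curvature * (x1 - x0) * rng.standard_normal(5) * 0.1
    ctrl[:, 0] = np.clip(ctrl[:, 0], z0, z1)
    ctrl[:, 2] = np.clip(ctrl[:, 2], x0, x1)
    cs = CubicSpline(t, ctrl, axis=0)
    return cs(np.linspace(0.0, 1.0, n_pts))


def make_vessels(n_tubes: int, tube_diameter: float, grid: GridSpec, seed: int,
                 *, orientation: str = "random", curvature: float = 1.0,
                 amplitude: float = 1.0,
                 z_band: tuple[float, float] | None = None,
                 margin: float | None = None,
                 min_separation: float = 0.0
                 ) -> tuple[VolumeStack, GroundTruth]:
    """Vessel-like tubes: smooth 3D curves of constant circular cross-section.

    ``orientation='z'`` renders straight axial tubes (every xy cross-section
    is then a disc of the stated diameter); ``'random'`` renders smooth
    curves running across the volume.  The tube edge is anti-aliased over one
    lateral voxel, so a cross-section FWHM equals the diameter to within half
    a voxel.
    """
    if n_tubes < 0:
        raise ParameterError("n_tubes must be >= 0")
    if tube_diameter <= 0:
        raise ParameterError("tube_diameter must be positive")
    vol = grid.empty()
    if n_tubes == 0:
        return vol, GroundTruth(centers=np.empty((0, 3)), extra={"curves": []})
    radius = tube_diameter / 2.0
    if margin is None:
        margin = radius  # lateral inset of tube axes from the grid faces
    if min((b[1] - b[0]) for b in grid.bounds()[1:]) < max(tube_diameter, 2 * margin):
        raise ParameterError("grid lateral extent smaller than one tube diameter")
    rng = _rng(seed, "vessels")
    bounds = grid.bounds()
    if z_band is not None:
        # confine tubes to an axial band (e.g. inside an illumination slab)
        bounds = [(max(bounds[0][0], z_band[0]), min(bounds[0][1], z_band[1]))] + bounds[1:]
        if bounds[0][1] <= bounds[0][0]:
            raise ParameterError("z_band does not intersect the grid")
    curves = []
    for _ in range(n_tubes):
        for _attempt in range(1000):
            if orientation == "z":
                (z0, z1), (y0, y1), (x0, x1) = bounds
                y = rng.uniform(y0 + margin, y1 - margin)
                x = rng.uniform(x0 + margin, x1 - margin)
                zpts = np.linspace(z0, z1, max(grid.shape[0] * 2, 8))
                curve = np.column_stack([zpts, np.full_like(zpts, y),
                                         np.full_like(zpts, x)])
            else:
                inset = [(bounds[0][0] + radius, bounds[0][1] - radius)] + \
                    [(b[0] + margin, b[1] - margin) for b in bounds[1:]]
                curve = _smooth_curve(rng, inset, 200, curvature)
            mid = curve[len(curve) // 2]
            if min_separation <= 0 or all(
                    np.linalg.norm(c[len(c) // 2][1:] - mid[1:]) >= min_separation
                    for c in curves):
                break
        else:
            raise ParameterError("could not place tubes with the requested separation")
        curves.append(curve)

    # rasterise: distance from each voxel (physical coords) to the curve samples
    step = min(grid.voxel_size[1:]) / 2.0
    zz = grid.coords(0)
    yy = grid.coords(1)
    xx = grid.coords(2)
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    pts = np.column_stack([Z.ravel(), Y.ravel(), X.ravel()])
    edge = min(grid.voxel_size[1:])  # anti-aliasing width, one lateral voxel
    for curve in curves:
        seg = np.diff(curve, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        n_sub = np.maximum(1, np.ceil(seglen / step)).astype(int)
        dense = [curve[0:1]]
        for i, k in enumerate(n_sub):
            frac = (np.arange(1, k + 1) / k)[:, None]
            dense.append(curve[i] + frac * seg[i])
        dense = np.vstack(dense)
        tree = cKDTree(dense)
        d, _ = tree.query(pts, workers=1, distance_upper_bound=radius + 2 * edge)
        occ = np.clip((radius - d) / edge + 0.5, 0.0, 1.0)
        occ[~np.isfinite(d)] = 0.0
        vol.values += occ.reshape(grid.shape)
    np.clip(vol.values, 0.0, 1.0, out=vol.values)
    vol.values *= amplitude
    centers = np.array([c[len(c) // 2] for c in curves])
    truth = GroundTruth(centers=centers, sizes=np.full(n_tubes, tube_diameter),
                        extra={"curves": curves})
    return vol, truth


def make_nuclei_timeseries(n_cells: int, frames: int, frame_interval: float,
                           transient_decay: float, firing_rate: float,
                           baseline: float, amplitude: float, grid: GridSpec,
                           seed: int, *, lateral_diameter: float = 5.0,
                           axial_diameter: float = 10.0,
                           silent_fraction: float = 0.2,
                           min_separation: float | None = None,
                           ) -> tuple[TimeSeriesStack, GroundTruth]:
    """Blinking-nuclei calcium phantom.

    Each nucleus is a static ellipsoidal blob (FWHM = the stated diameters)
    whose intensity follows ``baseline + amplitude * (spike train convolved
    with a one-sided exponential of time constant transient_decay)``.  Spike
    trains are Poisson at ``firing_rate``; a fraction of cells is silent
    (constant at baseline).  Truth records centres, traces, spike times and
    the active flags.
    """
    if frames < 2:
        raise ParameterError("frames must be >= 2")
    if frame_interval <= 0 or transient_decay <= 0:
        raise ParameterError("times must be positive")
    if firing_rate < 0:
        raise ParameterError("firing_rate must be >= 0")
    if not 0.0 <= silent_fraction <= 1.0:
        raise ParameterError("silent_fraction must be in [0, 1]")
    rng_geo = _rng(seed, "nuclei-geometry")
    rng_act = _rng(seed, "nuclei-activity")
    if min_separation is None:
        min_separation = 1.5 * lateral_diameter
    bounds = grid.bounds()
    lo = np.array([b[0] for b in bounds]) + np.array([axial_diameter, lateral_diameter, lateral_diameter]) / 2
    hi = np.array([b[1] for b in bounds]) - np.array([axial_diameter, lateral_diameter, lateral_diameter]) / 2
    if np.any(hi <= lo):
        raise ParameterError("grid too small for the requested nuclei")
    centers = []
    scale = np.array([lateral_diameter / axial_diameter, 1.0, 1.0])  # anisotropy-normalised
    for _ in range(20000):
        if len(centers) == n_cells:
            break
        c = lo + (hi - lo) * rng_geo.random(3)
        if centers:
            d = np.linalg.norm((np.array(centers) - c) * scale, axis=1)
            if d.min() < min_separation:
                continue
        centers.append(c)
    if len(centers) < n_cells:
        raise ParameterError("could not place the requested nuclei; grid too crowded")
    centers = np.array(centers)

    n_silent = int(round(silent_fraction * n_cells))
    active = np.ones(n_cells, dtype=bool)
    if n_silent:
        active[rng_act.choice(n_cells, size=n_silent, replace=False)] = False

    t = frame_interval * np.arange(frames)
    kernel = np.exp(-t / transient_decay)  # unit peak, one-sided exponential
    traces = np.full((n_cells, frames), float(baseline))
    spike_times: list = []
    for i in range(n_cells):
        if not active[i] or firing_rate == 0:
            spike_times.append(np.empty(0))
            continue
        counts = rng_act.poisson(firing_rate * frame_interval, size=frames)
        conv = np.convolve(counts.astype(float), kernel)[:frames]
        traces[i] += amplitude * conv
        st = np.repeat(t, counts)
        spike_times.append(st)

    sig = np.array([axial_diameter, lateral_diameter, lateral_diameter]) / _FWHM
    # render static unit blobs once, scale by traces per frame
    blobs = []
    for c in centers:
        v = np.zeros(grid.shape, dtype=np.float32)
        _render_blob(v, grid, c, sig)
        nzi = np.nonzero(v)
        blobs.append((nzi, v[nzi]))
    series = np.zeros((frames,) + grid.shape, dtype=np.float32)
    for i, (nzi, vals) in enumerate(blobs):
        for f in range(frames):
            series[f][nzi] += vals * traces[i, f]
    stack = TimeSeriesStack(series, frame_interval, grid.voxel_size, grid.z_offset)
    truth = GroundTruth(centers=centers,
                        sizes=np.tile([axial_diameter, lateral_diameter, lateral_diameter],
                                      (n_cells, 1)),
                        traces=traces, spike_times=spike_times, active=active)
    return stack, truth


def make_flowing_particles(n: int, speed_field, frames: int, volume_rate: float,
                           grid: GridSpec, seed: int, *,
                           particle_diameter: float = 2.0,
                           amplitude: float = 1.0,
                           ) -> tuple[TimeSeriesStack, GroundTruth]:
    """Particles advected through a velocity field, one rendered volume per frame.

    ``speed_field`` is either a constant velocity ``(vz, vy, vx)`` in µm/s or
    a callable ``pos -> velocity`` (µm, µm/s).  Positions integrate the field
    with one Euler step per frame (exact for uniform flow); truth stores the
    full trajectories.  Per-frame displacement should stay below a small
    fraction of the volume extent for tracking to be meaningful.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if frames < 1:
        raise ParameterError("frames must be >= 1")
    if volume_rate <= 0:
        raise ParameterError("volume_rate must be positive")
    if callable(speed_field):
        vel = speed_field
    else:
        v0 = np.asarray(speed_field, dtype=float)
        vel = lambda pos: v0  # noqa: E731
    rng = _rng(seed, "flow")
    bounds = grid.bounds()
    margin = particle_diameter
    lo = np.array([b[0] + margin for b in bounds])
    hi = np.array([b[1] - margin for b in bounds])
    if np.any(hi <= lo):
        raise ParameterError("grid too small for the requested particles")
    pos = lo + (hi - lo) * rng.random((n, 3))
    dt = 1.0 / volume_rate
    traj = np.empty((n, frames, 3))
    sig = np.full(3, particle_diameter / _FWHM)
    series = np.zeros((frames,) + grid.shape, dtype=np.float32)
    for f in range(frames):
        traj[:, f] = pos
        for i in range(n):
            _render_blob(series[f], grid, pos[i], sig)
        pos = pos + np.array([vel(p) for p in pos]) * dt
    series *= amplitude
    stack = TimeSeriesStack(series, dt, grid.voxel_size, grid.z_offset)
    truth = GroundTruth(centers=traj[:, 0].copy(),
                        sizes=np.full(n, particle_diameter),
                        trajectories=traj)
    return stack, truth


def make_calibration_grid(n_lenslets: tuple[int, int], pitch_px: float,
                          rotation_deg: float, shape: tuple[int, int], seed: int,
                          *, center: tuple[float, float] | None = None,
                          spot_sigma_px: float = 2.0,
                          noise: float = 0.0) -> np.ndarray:
    """Synthetic uniform-illumination lenslet calibration frame.

    Bright Gaussian spots on a rotated square lattice of the given sub-pixel
    pitch; optional multiplicative noise.  Used to exercise rectification.
    """
    H, W = shape
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    th = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    nv, nu = n_lenslets
    iv = np.arange(nv) - (nv - 1) / 2.0
    iu = np.arange(nu) - (nu - 1) / 2.0
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:H, 0:W]
    for i in iv:
        for j in iu:
            cy, cx = np.array(center) + pitch_px * (R @ np.array([i, j]))
            if not (0 <= cy < H and 0 <= cx < W):
                continue
            img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spot_sigma_px ** 2))
    if noise > 0:
        rng = _rng(seed, "calibration")
        img *= 1.0 + noise * rng.standard_normal(shape)
        np.clip(img, 0.0, None, out=img)
    return img


# ---------------------------------------------------------------------------
# illumination and noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IlluminationProfile:
    """Axial excitation profile: a selective slab or wide-field illumination.

    In selective mode the slab is centred at ``z_center`` with axial extent
    ``z_extent`` (full width of the w = 0.5 region) and a raised-cosine
    falloff whose 10-90% distance is ``edge_width``.  Wide-field mode has
    unit weight everywhere.
    """

    mode: str = "selective"
    z_center: float = 0.0
    z_extent: float = 100.0
    edge_width: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("wide-field", "selective"):
            raise ParameterError(f"unknown illumination mode {self.mode!r}")
        if self.mode == "selective" and self.z_extent <= 0:
            raise ParameterError("z_extent must be positive in selective mode")
        if self.edge_width < 0:
            raise ParameterError("edge_width must be >= 0")

    def weight(self, z) -> np.ndarray:
        """Excitation weight in [0, 1] at object depth z (µm)."""
        z = np.asarray(z, dtype=float)
        if self.mode == "wide-field":
            return np.ones_like(z)
        d = np.abs(z - self.z_center) - self.z_extent / 2.0
        if self.edge_width == 0:
            return (d <= 0).astype(float)
        # raised-cosine ramp whose 10-90% distance equals edge_width
        ramp = self.edge_width / 0.5903
        u = np.clip(d / ramp + 0.5, 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * u))


@dataclass(frozen=True)
class NoiseSpec:
    """Scale-then-Poisson background noise: λ is the mean photon count/pixel."""

    target_mean_lambda: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_mean_lambda <= 0:
            raise ParameterError("target_mean_lambda must be positive")


def apply_illumination(volume: VolumeStack, profile: IlluminationProfile) -> VolumeStack:
    """Multiply each z-plane by the excitation weight of the profile.

    Wide-field mode returns the input unchanged (same values).
    """
    if profile.mode == "wide-field":
        return volume.copy_with(volume.values.copy())
    w = profile.weight(volume.z_coords)
    return volume.copy_with(volume.values * w[:, None, None])


def add_poisson_background(lf_image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Corrupt a raw light-field image with scaled Poisson noise.

    The image is globally rescaled so its mean equals ``target_mean_lambda``
    (photons per pixel), then every pixel is replaced by a Poisson draw with
    that pixel's value as its mean — so the noise is spatially correlated
    with the image.  Returns the noisy image in photon counts (float64).
    """
    img = np.asarray(lf_image, dtype=float)
    if np.any(img < 0):
        raise ParameterError("lf_image must be non-negative")
    mean = img.mean()
    if mean == 0:
        raise ParameterError("cannot scale an all-zero image to a target mean")
    scaled = img * (spec.target_mean_lambda / mean)
    rng = _rng(spec.seed, "poisson-background")
    return rng.poisson(scaled).astype(np.float64)
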