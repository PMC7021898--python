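"""Stack readers/writers, run configuration and the pipeline driver.

Volumes and time series travel as multi-page TIFF plus a JSON sidecar
(``<name>.json``) carrying the physical metadata (voxel sizes, frame
interval, z offset).  Voxel sizes are never silently assumed: a stack
without a sidecar and without config-supplied sizes is an error.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .errors import ConfigurationError, ParameterError
from .stacks import GridSpec, TimeSeriesStack, VolumeStack

__all__ = ["read_stack", "write_stack", "load_config", "run_pipeline"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path, stack, *, dtype: str = "float32") -> dict:
    """Write a VolumeStack/TimeSeriesStack as multi-page TIFF + JSON sidecar.

    ``dtype='uint16'`` min-max scales to the full 16-bit range and records
    the scale factor in the sidecar; ``float32`` stores values verbatim.
    """
    path = Path(path)
    values = stack.values
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "z_offset_um": stack.z_offset,
        "axes": "TZYX" if values.ndim == 4 else "ZYX",
    }
    if isinstance(stack, TimeSeriesStack):
        meta["frame_interval_s"] = stack.frame_interval
    if dtype == "uint16":
        vmax = float(values.max())
        scale = 65535.0 / vmax if vmax > 0 else 1.0
        data = np.clip(values * scale, 0, 65535).astype(np.uint16)
        meta["intensity_scale"] = scale
    elif dtype == "float32":
        data = values.astype(np.float32)
    else:
        raise ParameterError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data.reshape((-1,) + data.shape[-2:]),
                     photometric="minisblack", metadata={"axes": meta["axes"]})
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return meta


def read_stack(path, *, voxel_size=None, frame_interval=None, z_offset=None,
               n_frames: int | None = None):
    """Read a TIFF stack with its sidecar (or config-supplied) metadata.

    Returns a :class:`VolumeStack` or, when the metadata declares TZYX axes
    (or ``n_frames`` is given), a :class:`TimeSeriesStack`.  Values are
    widened to float32 so 16-bit data at 65535 cannot overflow downstream.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path)).astype(np.float32)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    vs = voxel_size or meta.get("voxel_size_um")
    if vs is None:
        raise ConfigurationError(
            f"no voxel size for {path.name}: provide voxel_size or a JSON sidecar "
            "with 'voxel_size_um' (sizes are never assumed)")
    zo = z_offset if z_offset is not None else meta.get("z_offset_um", 0.0)
    axes = meta.get("axes")
    fi = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if n_frames is None and axes == "TZYX" and data.ndim == 3:
        raise ConfigurationError(
            f"{path.name} declares TZYX axes but the page count cannot be split "
            "without 'n_frames'")
    if data.ndim == 4 or n_frames is not None:
        if n_frames is not None and data.ndim == 3:
            data = data.reshape(n_frames, -1, *data.shape[-2:])
        if fi is None:
            raise ConfigurationError(
                f"no frame interval for time series {path.name}: provide "
                "frame_interval or a sidecar with 'frame_interval_s'")
        return TimeSeriesStack(data, float(fi), tuple(vs), float(zo))
    return VolumeStack(data, tuple(vs), float(zo))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "optics", "illumination", "phantom", "noise",
         "reconstruction", "metrics", "activity", "tracking"},
    "optics": {"magnification", "numerical_aperture", "emission_wavelength",
               "medium_refractive_index", "lenslet_pitch", "lenslet_focal_length",
               "camera_pixel_pitch", "lenslet_grid", "supersampling", "psf_model",
               "oversampling", "max_defocus", "z_min", "z_max", "z_step"},
    "illumination": {"mode", "z_center", "z_extent", "edge_width"},
    "phantom": {"kind", "n", "diameter_um", "orientation", "curvature", "amplitude",
                "frames", "frame_interval_s", "transient_decay_s", "firing_rate_hz",
                "baseline", "silent_fraction", "speed_um_per_s", "volume_rate"},
    "noise": {"target_mean_lambda"},
    "reconstruction": {"z_extent", "z_sampling", "iterations", "z_center",
                       "dark_counts"},
    "metrics": {"moving_average_window"},
    "activity": {"lateral_diameter", "axial_diameter", "threshold", "k", "onset_frame",
                 "t_window"},
    "tracking": {"spot_diameter", "threshold", "max_displacement", "min_length"},
}


def _validate(cfg: dict, section: str = "") -> None:
    allowed = _SCHEMA[section]
    for key, val in cfg.items():
        if key not in allowed:
            raise ConfigurationError(
                f"unknown key {key!r} in config section {section or '<root>'!r}")
        if key in _SCHEMA and isinstance(val, dict):
            _validate(val, key)


def load_config(path) -> dict:
    """Load and validate the toolkit-wide YAML configuration.

    Unknown keys anywhere are rejected; numeric invariants are enforced by
    the owning module's constructors before any computation runs.
    """
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config root must be a mapping")
    _validate(cfg)
    return cfg


def optics_from_config(cfg: dict):
    from .optics import OpticalConfig
    sect = dict(cfg.get("optics", {}))
    for k in ("z_min", "z_max", "z_step"):
        if k not in sect:
            raise ConfigurationError(f"optics section requires {k}")
    z = np.arange(sect.pop("z_min"), sect.pop("z_max") + 1e-9, sect.pop("z_step"))
    if "lenslet_grid" in sect:
        sect["lenslet_grid"] = tuple(sect["lenslet_grid"])
    return OpticalConfig(z_planes=tuple(z), **sect)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict, stages: list[str], output_dir=None) -> dict:
    """Run simulate -> reconstruct -> analyze stages from a validated config.

    Each stage writes its outputs under ``output_dir`` plus a provenance
    record (config hash, seed, version, wall time).  Deterministic stages
    reproduce their outputs bit-for-bit on rerun with identical config.
    """
    from . import metrics as metrics_mod
    from . import optics as optics_mod
    from . import phantoms, reconstruction

    order = ["psf", "simulate", "reconstruct", "metrics"]
    unknown = set(stages) - set(order)
    if unknown:
        raise ParameterError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in order if s in stages]
    _validate(config)
    outdir = Path(output_dir or config.get("output_dir", "svim_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    prov = {"config_hash": _config_hash(config), "seed": seed,
            "version": __version__, "stages": {}}
    state: dict = {}
    for stage in stages:
        t0 = time.perf_counter()
        if stage == "psf":
            ocfg = optics_from_config(config)
            psf = optics_mod.compute_lf_psf(ocfg)
            optics_mod.save_psf(psf, outdir / "psf.h5")
            state["psf"] = psf
        elif stage == "simulate":
            psf = state.get("psf") or optics_mod.load_psf(outdir / "psf.h5")
            state["psf"] = psf
            grid = psf.object_grid()
            ph = config.get("phantom", {"kind": "beads", "n": 3, "diameter_um": 0.5})
            kind = ph.get("kind", "beads")
            if kind == "beads":
                vol, truth = phantoms.make_beads(ph.get("n", 3), ph.get("diameter_um", 0.5),
                                                 grid, seed, amplitude=ph.get("amplitude", 1.0))
            elif kind == "vessels":
                vol, truth = phantoms.make_vessels(ph.get("n", 3), ph.get("diameter_um", 5.0),
                                                   grid, seed,
                                                   orientation=ph.get("orientation", "random"),
                                                   curvature=ph.get("curvature", 1.0),
                                                   amplitude=ph.get("amplitude", 1.0))
            else:
                raise ConfigurationError(f"pipeline cannot simulate phantom kind {kind!r}")
            if "illumination" in config:
                vol = phantoms.apply_illumination(
                    vol, phantoms.IlluminationProfile(**config["illumination"]))
            lf = optics_mod.forward_project(vol, psf)
            if "noise" in config:
                lf = phantoms.add_poisson_background(
                    lf, phantoms.NoiseSpec(config["noise"]["target_mean_lambda"], seed))
            lf_stack = VolumeStack(lf[None], (1.0, psf.config.camera_pixel_pitch,
                                              psf.config.camera_pixel_pitch))
            write_stack(outdir / "lf.tif", lf_stack, dtype="float32")
            (outdir / "truth.json").write_text(json.dumps(
                {"centers_um": truth.centers.tolist()}, indent=1))
            state["lf"] = lf
        elif stage == "reconstruct":
            psf = state.get("psf") or optics_mod.load_psf(outdir / "psf.h5")
            lf = state.get("lf")
            if lf is None:
                lf = read_stack(outdir / "lf.tif",
                                voxel_size=(1.0, 1.0, 1.0)).values[0]
            rc = dict(config.get("reconstruction", {}))
            dark = rc.pop("dark_counts", 0.0)
            if dark:
                lf = reconstruction.subtract_background(lf, dark)
            if "z_extent" not in rc:
                z = psf.z_planes
                rc["z_extent"] = float(z[-1] - z[0])
                rc["z_sampling"] = float(z[1] - z[0]) if z.size > 1 else 1.0
            vol, log_ = reconstruction.deconvolve(
                lf, psf, reconstruction.ReconstructionConfig(**rc), return_log=True)
            write_stack(outdir / "recon.tif", vol, dtype="float32")
            prov["stages"].setdefault("reconstruct", {})["objective"] = log_["objective"]
            state["recon"] = vol
        elif stage == "metrics":
            vol = state.get("recon") or read_stack(outdir / "recon.tif")
            w = config.get("metrics", {}).get("moving_average_window", 1)
            profile = metrics_mod.contrast_z_profile(vol, w)
            import pandas as pd
            pd.DataFrame({"z_um": profile.z, "contrast": profile.values}).to_csv(
                outdir / "metrics.csv", index=False)
        prov["stages"].setdefault(stage, {})["wall_time_s"] = time.perf_counter() - t0
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1))
    return prov
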