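"""Core intensity containers: 3D volumes and 4D time series with physical metadata.

All arrays are indexed ``(z, y, x)`` or ``(t, z, y, x)``; physical sizes are in
micrometres and times in seconds.  ``z = 0`` is the native focal plane of the
detection objective, positive z toward the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

__all__ = ["VolumeStack", "TimeSeriesStack", "GridSpec"]


@dataclass
class VolumeStack:
    """A 3D intensity volume on a regular (z, y, x) grid.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in µm.
    z_offset : float
        z of the first plane relative to the native focal plane, µm.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ParameterError(f"VolumeStack expects a 3D array, got {self.values.ndim}D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be three positive numbers, got {self.voxel_size}")
        if self.values.size and float(self.values.min()) < 0:
            raise ParameterError("VolumeStack values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def z_coords(self) -> np.ndarray:
        """z positions of the planes in µm."""
        return self.z_offset + self.voxel_size[0] * np.arange(self.values.shape[0])

    def copy_with(self, values: np.ndarray) -> "VolumeStack":
        return replace(self, values=values)


@dataclass
class TimeSeriesStack:
    """A 4D (t, z, y, x) intensity time series."""

    values: np.ndarray
    frame_interval: float
    voxel_size: tuple[float, float, float]
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ParameterError(f"TimeSeriesStack expects a 4D array, got {self.values.ndim}D")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be three positive numbers, got {self.voxel_size}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def frame(self, t: int) -> VolumeStack:
        return VolumeStack(self.values[t], self.voxel_size, self.z_offset)


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid on which phantoms are rendered.

    ``shape`` is (nz, ny, nx); ``voxel_size`` is (dz, dy, dx) µm; ``z_offset``
    places the first plane relative to the native focal plane.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ParameterError(f"grid shape must be three positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be three positive numbers, got {self.voxel_size}")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid in µm along (z, y, x)."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis (µm).

        Lateral axes are centred on zero; z uses ``z_offset``.
        """
        n = self.shape[axis]
        d = self.voxel_size[axis]
        if axis == 0:
            return self.z_offset + d * np.arange(n)
        return d * (np.arange(n) - (n - 1) / 2.0)

    def empty(self) -> VolumeStack:
        return VolumeStack(np.zeros(self.shape, dtype=np.float64), self.voxel_size, self.z_offset)

    def bounds(self) -> list[tuple[float, float]]:
        """Physical [min, max] of voxel centres per axis."""
        return [(float(self.coords(a)[0]), float(self.coords(a)[-1])) for a in range(3)]
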