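"""Presentation-only helpers: projections and display stretches.

These implement the figure-making conventions (percentile-saturated min-max
stretch, averaged-intensity projections, 16-bit scaling) and are kept out of
every quantitative code path: contrast and FWHM are computed on unstretched
data, where only exact positive rescaling (which they are invariant to) is
ever applied.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .stacks import VolumeStack

__all__ = ["average_projection", "max_projection", "percentile_stretch", "to_uint16"]


def average_projection(volume: VolumeStack, axis: int = 0) -> np.ndarray:
    """Averaged-intensity projection (the default for figures: it represents
    the background of 3D data more faithfully than a maximum projection)."""
    return volume.values.mean(axis=axis)


def max_projection(volume: VolumeStack, axis: int = 0) -> np.ndarray:
    return volume.values.max(axis=axis)


def percentile_stretch(image: np.ndarray, saturation: float = 0.4) -> np.ndarray:
    """Min-max display stretch with a saturated percentile tail.

    ``saturation`` is the total percentage of pixels allowed to clip
    (split between the two tails).  Display only — never quantify on this.
    """
    if not 0 <= saturation < 100:
        raise ParameterError("saturation must be a percentage in [0, 100)")
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [saturation / 2, 100 - saturation / 2])
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def to_uint16(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale to fill the 16-bit range; returns (scaled, scale_factor)."""
    img = np.asarray(image, dtype=float)
    vmax = img.max()
    scale = 65535.0 / vmax if vmax > 0 else 1.0
    return np.clip(img * scale, 0, 65535).astype(np.uint16), scale
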