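"""Exception hierarchy shared across the toolkit."""


class SvimError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(SvimError, ValueError):
    """A configuration value is non-physical or inconsistent."""


class ZRangeError(SvimError, ValueError):
    """A requested z-plane lies outside the validity range of the PSF model."""


class GridMismatchError(SvimError, ValueError):
    """Two arrays or grids that must share a geometry do not."""


class CalibrationError(SvimError, ValueError):
    """Lenslet-grid calibration could not be estimated from the image."""


class GeometryError(SvimError, ValueError):
    """A requested sampling geometry falls outside the available data."""


class MeasurementError(SvimError, ValueError):
    """A quantitative measurement is undefined on the given data."""


class ParameterError(SvimError, ValueError):
    """An operation parameter violates its documented precondition."""
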