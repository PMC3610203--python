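"""Typed exceptions raised across the package."""


class ScarqError(Exception):
    """Base class for all scarq errors."""


class GeometryError(ScarqError, ValueError):
    """Invalid or degenerate contour geometry (e.g. endocardium not inside epicardium)."""


class MappingError(ScarqError, ValueError):
    """The stack cannot be mapped onto the AHA segment model (e.g. fewer than 3 slices)."""


class CalibrationError(ScarqError, ValueError):
    """Invalid intensity calibration (core intensity must exceed remote intensity)."""


class InputError(ScarqError, ValueError):
    """Malformed or inconsistent input files."""
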