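"""Exception hierarchy for fiberfold.

All domain errors derive from :class:`FiberfoldError` so batch drivers can
catch one type, flag the offending frame and keep going.
"""


class FiberfoldError(Exception):
    """Base class for all fiberfold errors."""


class CalibrationError(FiberfoldError):
    """Powder-ring calibration failed (e.g. no ring above the noise floor)."""


class CalibrationRequiredError(FiberfoldError):
    """A d-spacing conversion was requested from an uncalibrated geometry."""


class DegenerateInputError(FiberfoldError):
    """Input carries no usable signal (e.g. a flat, zero-variance image)."""


class OrientationUndeterminedError(FiberfoldError):
    """The pattern is too isotropic for an orientation estimate."""


class GeometryError(FiberfoldError):
    """A box, quadrant or center fell outside the usable image area."""


class FormatError(FiberfoldError):
    """An image file could not be read or has an unsupported layout."""


class SettingsError(FiberfoldError):
    """The JSON settings file is malformed or carries unknown keys."""
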