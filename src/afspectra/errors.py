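"""Exception types shared across the package."""


class AFSpectraError(Exception):
    """Base class for all package errors."""


class CubeFormatError(AFSpectraError):
    """A channel file is malformed or inconsistent with its siblings."""


class AxisMismatchError(AFSpectraError):
    """Channel count or wavelength axis disagrees with the data."""


class IntensityRangeError(AFSpectraError):
    """Pixel values exceed the 12-bit range [0, 4095]."""


class SceneConfigError(AFSpectraError):
    """A synthetic scene cannot be realised from its configuration."""


class BandConfigError(AFSpectraError):
    """A spectral band maps to no channel on the wavelength axis."""


class CalibrationError(AFSpectraError):
    """Microsphere calibration could not be computed."""


class ROIError(AFSpectraError):
    """An ROI definition is invalid (bounds, label, or shape)."""


class InsufficientDataError(AFSpectraError):
    """Too few sampling units for the requested statistic."""
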