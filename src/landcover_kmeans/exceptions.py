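"""Exception hierarchy for the toolkit.

All domain errors derive from :class:`LandcoverError` so callers (and the
CLI) can distinguish input problems from computation failures.
"""


class LandcoverError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(LandcoverError, ValueError):
    """An argument violates a documented precondition."""


class RasterFormatError(LandcoverError, IOError):
    """A raster file exists but does not match the expected layout."""


class BandConfigurationError(LandcoverError, ValueError):
    """The band-order configuration is inconsistent with the request."""


class UnsupportedBandError(LandcoverError, ValueError):
    """An index requires a spectral band the sensor does not record."""
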