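"""Exception hierarchy shared across the package."""


class MsfasimError(Exception):
    """Base class for all package-specific errors."""


class GridError(MsfasimError, ValueError):
    """Wavelength grids are incompatible or invalid."""


class SpectralRangeError(MsfasimError, ValueError):
    """A requested wavelength range falls outside the available support."""


class SpectraFormatError(MsfasimError, ValueError):
    """A spectra CSV file violates the expected dialect."""


class ParameterError(MsfasimError, ValueError):
    """A numeric parameter is out of its valid domain."""


class ShapeError(MsfasimError, ValueError):
    """Array dimensions do not agree."""


class GeometryError(MsfasimError, ValueError):
    """Image dimensions are incompatible with the mosaic geometry."""


class LayoutError(MsfasimError, ValueError):
    """A mosaic layout is invalid or a band is missing from it."""


class DegenerateInputError(MsfasimError, ValueError):
    """An input is degenerate (zero vector, dead band, ...)."""


class RegularizationError(MsfasimError, ValueError):
    """A linear solve failed; a positive noise variance is required."""


class SearchSizeError(MsfasimError, ValueError):
    """An exhaustive search would exceed the configured combination cap."""


class ConfigError(MsfasimError, ValueError):
    """A run configuration failed validation."""
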