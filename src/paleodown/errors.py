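"""Exception hierarchy shared across the package."""


class PaleodownError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PaleodownError):
    """Grids are geometrically incompatible (spec mismatch, misalignment)."""


class FormatError(PaleodownError):
    """A file is not in the expected raster format or CRS."""


class UnitError(PaleodownError):
    """A grid carries the wrong physical units for the operation."""


class ConfigurationError(PaleodownError):
    """Inputs are structurally valid but the requested operation is impossible."""


class NumericalError(PaleodownError):
    """A linear system is singular or otherwise numerically unsolvable."""


class UndefinedCorrelationError(PaleodownError):
    """Correlation requested on data with zero variance or too few points."""
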