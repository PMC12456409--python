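"""Exception hierarchy.

Every failure mode the pipeline distinguishes maps to one of these classes so
callers (and the CLI) can react by category: bad user parameters, malformed
input files, inconsistent data values, or a geometric/segmentation failure on
an otherwise valid image.
"""


class DCMigrationError(Exception):
    """Base class for all package errors."""


class ParameterError(DCMigrationError, ValueError):
    """A parameter is outside its valid range or combination."""


class FormatError(DCMigrationError, ValueError):
    """An input file does not conform to the expected format (e.g. missing column)."""


class DataError(DCMigrationError, ValueError):
    """Input values are inconsistent or insufficient for the requested analysis."""


class GeometryError(DCMigrationError, ValueError):
    """Cell/nucleus geometry is degenerate (empty partition, nucleus outside cell, ...)."""


class SegmentationError(DCMigrationError, ValueError):
    """Segmentation produced no usable foreground object."""


class ConfigurationError(DCMigrationError, ValueError):
    """Required configuration (units, calibration, pixel size) is missing."""
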