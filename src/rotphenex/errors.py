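"""Exception hierarchy; CLI exit codes map onto these classes."""


class RotPhenexError(Exception):
    """Base class for all package errors."""


class ConfigError(RotPhenexError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class DataError(RotPhenexError):
    """Malformed or missing input data (CLI exit code 3)."""


class InvalidArgumentError(RotPhenexError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(DataError):
    """Zero-area or otherwise degenerate geometric input."""


class AnnotationFormatError(DataError):
    """An annotation file does not follow its declared dialect."""


class PlacementError(RotPhenexError):
    """Synthetic scene could not place all objects under its constraints."""


class UndefinedMetricError(InvalidArgumentError):
    """A metric is undefined for the given inputs (e.g. no ground truth)."""
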