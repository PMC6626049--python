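"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`AxonQuantError`,
so callers (and the CLI, which maps domain errors to exit code 1) can catch one type.
"""


class AxonQuantError(Exception):
    """Base class for all domain errors raised by axonquant."""


class ParameterError(AxonQuantError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class CalibrationError(AxonQuantError):
    """A stack without physical voxel sizes and no override to supply them."""


class GeometryError(AxonQuantError):
    """Scene/stack geometry mismatch (field of view too small, bad axis, ...)."""


class ShapeError(AxonQuantError, ValueError):
    """Array shape mismatch between stages that must be voxel-aligned."""


class ParseError(AxonQuantError):
    """Malformed tabular input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NormalizationError(AxonQuantError):
    """Baseline normalization impossible (zero or undefined baseline mean)."""


class MissingDataError(AxonQuantError):
    """An operation hit missing (unacquired) positions it cannot tolerate."""


class ConfigError(AxonQuantError):
    """Invalid run configuration; message lists every violation found."""
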