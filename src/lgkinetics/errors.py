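"""Exception hierarchy for the lymph-gland kinetics pipeline.

Every error raised on bad user input derives from :class:`ValidationError`
so the CLI can map the whole family to exit code 2.
"""


class ValidationError(ValueError):
    """Base class for all input-validation failures."""


class FormatError(ValidationError):
    """A file does not conform to the expected tabular/JSON schema."""


class DataError(ValidationError):
    """Structurally valid input with impossible values (e.g. duplicate frames)."""


class ConfigError(ValidationError):
    """Unknown or out-of-range run-configuration key."""


class ParameterError(ValidationError):
    """Invalid parameter passed to a generator or analysis operation."""


class GeometryError(ValidationError):
    """Invalid organ geometry (degenerate polygon, non-unit axis, ...)."""


class InsufficientDataError(ValidationError):
    """Too few usable frames/records for the requested estimate."""


class DegenerateTrackError(DataError):
    """Both channels constant and equal; min-max normalization undefined."""
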