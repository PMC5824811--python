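"""Exception hierarchy.

Every error raised by the package derives from :class:`SynaptofluxError` so
callers can catch pipeline failures with a single except clause.
"""


class SynaptofluxError(Exception):
    """Base class for all package errors."""


class ValidationError(SynaptofluxError):
    """Inputs violate a documented precondition (shapes, counts, ranges)."""


class SchemaError(ValidationError):
    """A table does not match its named CSV schema."""


class GenerationError(SynaptofluxError):
    """Synthetic-data generation failed (e.g. spot placement exhausted retries)."""


class FitError(SynaptofluxError):
    """A model fit failed to converge or is degenerate."""


class UndefinedValueError(SynaptofluxError):
    """A requested statistic is mathematically undefined for these inputs."""


class CalibrationError(SynaptofluxError):
    """Instrument calibration (e.g. the GP G factor) cannot be computed."""
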