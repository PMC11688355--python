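"""Exception hierarchy for the toolkit.

Every typed failure raised by parsers, validators and pipeline stages derives
from :class:`ToolkitError`, so callers (and the CLI) can catch one base class.
"""


class ToolkitError(Exception):
    """Base class for all toolkit-specific errors."""


class ParseError(ToolkitError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(ToolkitError):
    """A file parsed but violates the expected schema (columns, keypoint count...)."""


class SamplingError(ToolkitError):
    """Frame timestamps are not uniformly sampled within tolerance."""


class ResamplingError(ToolkitError):
    """Requested resampling is not an integer decimation of the source rate."""


class AnnotationError(ToolkitError):
    """An expert annotation file contains invalid or duplicate intervals."""


class InsufficientDataError(ToolkitError):
    """Too few frames/samples for the requested computation."""


class WindowTooLongError(ToolkitError):
    """The selection window exceeds the length of the motion series."""


class EvaluationError(ToolkitError):
    """Selections and expert annotations are inconsistent (missing videos...)."""


class ConfigError(ToolkitError):
    """A simulation configuration is invalid."""
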