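"""Exception hierarchy shared across the pipeline.

Validation problems (bad values, malformed records) and dependency problems
(a stage invoked before its upstream output exists) are kept distinct so the
command-line layer can map them to different exit codes.
"""


class OhnofateError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OhnofateError, ValueError):
    """Invalid parameter values or malformed input records."""


class FormatError(ValidationError):
    """A file does not conform to its declared format."""


class DependencyError(OhnofateError):
    """A pipeline stage is missing a required upstream output."""


class TieError(ValidationError):
    """An ambiguous tie that requires explicit user input to resolve."""
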