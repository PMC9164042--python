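"""Exception hierarchy.

All user-facing failures derive from :class:`NsafPipeError` so callers (and
the CLI) can distinguish bad inputs from genuine bugs.
"""


class NsafPipeError(Exception):
    """Base class for all errors raised by this package."""


class ReportFormatError(NsafPipeError):
    """A report table is structurally malformed (e.g. missing column)."""


class ValidationError(NsafPipeError):
    """A value violates a domain invariant (range, uniqueness, shape)."""


class StudyDesignError(NsafPipeError):
    """Run keys do not conform to the declared study design."""


class ConfigError(NsafPipeError):
    """Pipeline configuration is invalid or references missing paths."""
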