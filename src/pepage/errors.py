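"""Exception hierarchy for the pipeline.

All package-specific failures derive from :class:`PepageError` so callers can
catch pipeline problems without swallowing programming errors.
"""


class PepageError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PepageError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(PepageError, ValueError):
    """A file does not conform to the pipeline's TSV dialect."""


class ValidationError(PepageError, ValueError):
    """Data violates a domain invariant (negative mass, stained > reference ...)."""


class NormalizationError(PepageError, RuntimeError):
    """Internal-standard normalization could not be carried out."""


class AnalysisError(PepageError, RuntimeError):
    """A statistical operation was called on inputs it cannot handle."""
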