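"""Exception hierarchy shared across the pipeline."""


class GaitForceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GaitForceError):
    """A force-record file violates the 19-column whitespace dialect."""


class SchemaError(GaitForceError):
    """A demographics table is missing mandatory columns or is inconsistent."""


class ConfigError(GaitForceError):
    """Invalid or contradictory configuration / generator parameters."""


class AnalysisError(GaitForceError):
    """A processing step cannot produce a meaningful result on this input."""


class NoGaitError(AnalysisError):
    """The force signal never exceeds the contact threshold."""


class InsufficientStridesError(AnalysisError):
    """Too few valid strides remain to summarize a subject."""
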