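"""Exception hierarchy shared across the package."""


class HeterosisError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HeterosisError, ValueError):
    """A file does not conform to its declared dialect."""


class DesignError(HeterosisError, ValueError):
    """The sample design is inconsistent with the analysis request."""


class ConfigError(HeterosisError, ValueError):
    """A configuration value is out of range or internally inconsistent."""


class InsufficientReplicationError(HeterosisError, ValueError):
    """Too few replicates for the requested statistical test."""


class UndefinedRatioError(HeterosisError, ZeroDivisionError):
    """A ratio whose denominator is zero."""


class InternalConsistencyError(HeterosisError, RuntimeError):
    """An arithmetically impossible state was reached; signals a bug."""
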