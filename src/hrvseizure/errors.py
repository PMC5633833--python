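"""Exception hierarchy used across the pipeline."""


class HRVError(ValueError):
    """Base class for all hrvseizure errors."""


class ConfigurationError(HRVError):
    """A generator or pipeline configuration violates its invariants."""


class ParameterError(HRVError):
    """An operation parameter is outside its valid range."""


class CoverageError(HRVError):
    """The RR series does not cover the span an operation needs."""


class InsufficientDataError(HRVError):
    """Too few beats/intervals for the requested metric."""
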