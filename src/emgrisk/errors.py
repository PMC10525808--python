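"""Exception hierarchy shared across the pipeline stages."""


class EmgRiskError(Exception):
    """Base class for all package errors."""


class ParameterError(EmgRiskError, ValueError):
    """An operation was called with invalid parameters (bad band, too-short
    signal, unknown model name, ...)."""


class DataError(EmgRiskError, ValueError):
    """Input data violates a contract (non-finite samples, ragged files,
    malformed headers)."""


class UndefinedFeatureError(EmgRiskError, ValueError):
    """A spectral feature is undefined for the given spectrum (zero total
    power, zero variance of spectral values)."""


class AlignmentError(EmgRiskError, ValueError):
    """Per-channel structures that must agree (ROI counts across the four
    channels of one trial) do not."""
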