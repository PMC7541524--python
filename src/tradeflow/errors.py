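"""Exception hierarchy shared across the package."""


class TradeflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TradeflowError):
    """A configuration object violates its invariants."""


class FormatError(TradeflowError):
    """An input file does not match the expected layout."""


class ValidationError(TradeflowError):
    """Data content violates a stated invariant."""


class AssemblyError(TradeflowError):
    """Design-matrix assembly failed (missing covariate cells etc.)."""


class FitError(TradeflowError):
    """Model fitting could not proceed (rank deficiency, bad likelihood)."""
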