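"""Package-specific exception types."""


class ConfigurationError(ValueError):
    """Raised when a parameter set or config file is inconsistent or invalid."""


class UndefinedEstimateError(ValueError):
    """Raised when a decoder's resultant vector vanishes and no orientation
    estimate exists (e.g. two equal-mass inputs with orthogonal preferences)."""


class UndefinedStatisticError(ValueError):
    """Raised when a circular statistic is undefined (all-zero tuning curve,
    degenerate variance in a correlation, ...)."""
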