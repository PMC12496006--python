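"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input object violates its documented invariants."""


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent or infeasible."""
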