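"""Exception types shared across the package."""


class CensusValidationError(ValueError):
    """Raised when census records violate a structural invariant."""


class ConfigurationError(ValueError):
    """Raised when a config file or column dialect cannot be resolved."""


class FittingError(RuntimeError):
    """Raised when no candidate vital-rate model can be fitted."""


class KernelAssemblyError(RuntimeError):
    """Raised when a projection kernel would contain invalid entries."""
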