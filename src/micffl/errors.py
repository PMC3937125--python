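"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when parameters, topology flags and inputs are mutually inconsistent."""


class NumericalError(RuntimeError):
    """Raised when an iterative numerical procedure fails to converge."""


class AnalysisError(RuntimeError):
    """Raised when an analysis is requested outside its domain of validity
    (e.g. a linear-noise expansion around an unstable fixed point)."""
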