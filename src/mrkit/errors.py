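"""Exception hierarchy for mrkit."""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrkitError):
    """A config file, column mapping, or parameter is unusable."""


class DataError(MrkitError):
    """Input data violate a hard precondition (empty, malformed, wrong scale)."""


class EstimationError(MrkitError):
    """An estimator cannot run (too few instruments, non-convergence)."""
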