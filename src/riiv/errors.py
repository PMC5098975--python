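"""Exception types raised by riiv."""


class RiivError(Exception):
    """Base class for all riiv errors."""


class ConfigurationError(RiivError):
    """A configuration (column map, option set, config file) is invalid."""


class DataValidationError(RiivError):
    """Input data violate a declared invariant (negative counts, bad types)."""


class DegenerateDataError(RiivError):
    """Data are formally valid but unusable (zero variance, single level)."""


class ParameterDomainError(RiivError):
    """A parameter value lies outside its mathematical domain."""


class ConvergenceError(RiivError):
    """MCMC convergence diagnostics exceeded their thresholds."""
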