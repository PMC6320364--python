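"""Exception hierarchy."""


class PathtimesError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PathtimesError, ValueError):
    """A model or configuration parameter violates its constraints."""


class DomainError(PathtimesError, ValueError):
    """Evaluation requested outside the domain of a tabulated object."""


class EstimationError(PathtimesError, RuntimeError):
    """An estimator has too little data to produce a meaningful result."""


class ConvergenceError(PathtimesError, RuntimeError):
    """A numerical scheme failed its convergence check."""


class ConfigError(PathtimesError, ValueError):
    """A JSON run configuration failed schema validation."""
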