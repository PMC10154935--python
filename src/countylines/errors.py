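"""Exception hierarchy shared across the package."""


class CountyLinesError(Exception):
    """Base class for all package errors."""


class FormatError(CountyLinesError, ValueError):
    """A file does not conform to its declared schema."""


class ValidationError(CountyLinesError, ValueError):
    """Data violate a domain invariant (nonpositive population, negative count, ...)."""


class ReconciliationError(CountyLinesError, ValueError):
    """Territory id sets of two inputs do not agree."""


class ConvergenceError(CountyLinesError, RuntimeError):
    """An optimiser failed to converge and the result cannot be trusted."""
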