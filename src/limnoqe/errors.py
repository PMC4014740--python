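"""Exception hierarchy shared by all limnoqe modules."""


class LimnoError(Exception):
    """Base class for all limnoqe errors."""


class FormatError(LimnoError, ValueError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(LimnoError, ValueError):
    """A record violates a physical invariant (e.g. negative concentration)."""


class DomainError(LimnoError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UsageError(LimnoError, ValueError):
    """The caller combined inputs in an unsupported way."""


class InsufficientDataError(LimnoError, ValueError):
    """Too few observations to carry out the requested computation."""


class DegenerateDesignError(LimnoError, ValueError):
    """A regression design matrix is rank-deficient (e.g. constant regressor)."""
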