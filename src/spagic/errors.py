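"""Exception hierarchy shared across modules."""


class SpagicError(Exception):
    """Base class for all package errors."""


class ParameterError(SpagicError, ValueError):
    """A user-supplied parameter violates its contract (k >= N, l <= 0, ...)."""


class ContractError(SpagicError, ValueError):
    """Array shapes or graph structure violate an operation's precondition."""


class AlignmentError(SpagicError, ValueError):
    """Expression and coordinate tables cannot be aligned on spot ids."""

    def __init__(self, message: str, missing_ids=()):
        super().__init__(message)
        self.missing_ids = list(missing_ids)


class EmptyMatrixError(SpagicError, ValueError):
    """Filtering removed every gene (or spot)."""


class NumericError(SpagicError, FloatingPointError):
    """Non-finite values where finite ones are required."""
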