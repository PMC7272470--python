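"""Exception types shared across the package."""


class DecoysimError(Exception):
    """Base class for package errors."""


class InvalidParameterError(DecoysimError, ValueError):
    """A model parameter violates its domain (negative rate, mean burst < 1, ...)."""


class StabilityError(DecoysimError, ArithmeticError):
    """The linearized drift matrix has an eigenvalue with non-negative real part."""


class TruncationError(DecoysimError, ValueError):
    """The truncated CME state space leaks too much probability."""


class NumericalError(DecoysimError, ArithmeticError):
    """A numerical routine failed (no bracket, singular solve, ...)."""
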