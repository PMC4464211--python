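"""Exception hierarchy."""


class TauraceError(Exception):
    """Base class for all package errors."""


class ParameterError(TauraceError, ValueError):
    """A distribution or reaction parameter violates its validity constraints."""


class DegenerateAError(ParameterError):
    """The Michaelis-Menten waiting-time parameters give A² = B² − k1·k2·[S] ≤ 0.

    At A = 0 the two exponentials of the density coincide (double root) and the
    two-exponential form degenerates; complex A never arises for positive rates
    but is rejected through the same check. Distinct from plain positivity
    violations so callers can tell a structurally impossible set from a typo.
    """


class InversionError(TauraceError, RuntimeError):
    """Numerical CDF inversion failed (bad quantile, bracket or iteration cap)."""


class ReactionSyntaxError(TauraceError, ValueError):
    """A reaction file line does not follow the documented grammar."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
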