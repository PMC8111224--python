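"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants.

    The message names the offending field.
    """


class FormatError(ValueError):
    """A spectrum or structure file could not be parsed.

    Carries the 1-based line number where parsing failed when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} ({loc})" if loc else message)
        self.path = path
        self.line = line


class FitError(RuntimeError):
    """A least-squares fit failed or the data admit no transition."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class ConvergenceError(FitError):
    """An iterative fit did not converge or became rank deficient."""


class SingularityError(ValueError):
    """A field evaluation point coincides with a charged atom."""
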