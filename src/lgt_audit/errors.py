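"""Exception types shared across the package.

All argument/contract violations derive from :class:`InvalidArgumentError`
(a ``ValueError``), so callers can catch one base class.
"""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class FrameError(InvalidArgumentError):
    """Sequence length is not a multiple of three where a codon frame is required."""


class UndefinedMetricError(InvalidArgumentError):
    """The metric is undefined for this input (e.g. an all-N sequence)."""


class DegenerateInputError(InvalidArgumentError):
    """Input is degenerate for the requested computation (e.g. zero variance everywhere)."""


class InfeasibleCompositionError(InvalidArgumentError):
    """The requested compositional target cannot be achieved under the codon table."""


class HitTableParseError(InvalidArgumentError):
    """A tabular hit file row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConsistencyError(InvalidArgumentError):
    """Conflicting assignments encountered while assembling ortholog groups."""
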