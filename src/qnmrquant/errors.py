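"""Exception hierarchy for qnmrquant.

All library errors derive from :class:`QnmrError` so callers (and the CLI)
can distinguish configuration problems from numerical failures.
"""


class QnmrError(Exception):
    """Base class for all qnmrquant errors."""


class InvalidParameterError(QnmrError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive T1)."""


class RegionError(QnmrError, ValueError):
    """An integration region is outside the spectral window or overlaps illegally."""


class DivisionGuardError(QnmrError, ZeroDivisionError):
    """A denominator that must be nonzero (reference area, weighted mass) is zero."""


class ParseError(QnmrError, ValueError):
    """A spectrum file could not be parsed; the message names the offending line."""


class FitError(QnmrError, RuntimeError):
    """A nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
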