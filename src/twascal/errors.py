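"""Exception hierarchy.

Errors are split by what the caller can do about them: ``DomainError`` for
arguments outside the model's valid range, ``DegenerateInputError`` for data
that is structurally valid but numerically unusable (zero variance, perfect
collinearity), ``FormatError`` for unparseable or inconsistent files, and
``RankError`` for regressions without enough distinct design points.
"""


class TwascalError(Exception):
    """Base class for all package errors."""


class DomainError(TwascalError, ValueError):
    """A parameter lies outside its mathematically valid domain."""


class DegenerateInputError(TwascalError, ValueError):
    """Input is numerically degenerate (e.g. a zero-variance vector)."""


class CollinearityError(DegenerateInputError):
    """Two vectors are perfectly collinear (|r| = 1)."""


class FormatError(TwascalError, ValueError):
    """A file does not conform to the declared dialect."""


class EmptyOverlapError(TwascalError, ValueError):
    """No model variants intersect the genotype matrix."""


class RankError(TwascalError, ValueError):
    """A regression design has too few distinct predictor values."""
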