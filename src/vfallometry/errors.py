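"""Exception hierarchy shared across the package.

All domain-specific failures derive from :class:`AllometryError`, so callers
(and the CLI) can catch one base class.  Most subclasses also derive from
``ValueError`` because they signal invalid argument values.
"""


class AllometryError(Exception):
    """Base class for all errors raised by vfallometry."""


class DomainError(AllometryError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (e.g. non-positive ST deviation or probability whose log is needed)."""


class ValidationError(AllometryError, ValueError):
    """A data structure violates its invariants (non-finite coefficients,
    duplicate table keys, malformed configuration, ...)."""


class DegenerateCurveError(AllometryError, ValueError):
    """A curve or design matrix is degenerate: zero exponent when inverting,
    or all ST values identical when fitting."""


class InsufficientDataError(AllometryError, ValueError):
    """Too few points for the requested operation (quadratic resampling and
    the two-parameter log-log fit both need at least three points)."""


class ExtrapolationError(AllometryError, ValueError):
    """The requested resampling window extends beyond the span of the data;
    the interpolant is never evaluated outside its knots."""


class ParseError(AllometryError, ValueError):
    """A delimited text file could not be parsed; the message carries the
    offending line number."""


class ProbabilityOverflowWarning(UserWarning):
    """The power law predicted a probability above 100%.  The model is an
    extrapolating power law, so this is reported as a warning, not an error."""
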