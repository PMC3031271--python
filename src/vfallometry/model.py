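"""Allometric law linking VF probability to ECG ST-segment deviation.

The core model is the power law

    P = 10 ** (delta + beta * log10(st))

where ``st`` is the unsigned ST-segment deviation in mm (standard ECG
calibration, 10 mm = 1 mV) and ``P`` is the probability of ventricular
fibrillation on a 0-100 percent scale.  In log-log coordinates the law is a
straight line with slope ``beta`` (the allometric exponent) and intercept
``delta``; each fitted (beta, delta) pair describes one cohort at one
follow-up horizon.

Base-10 logarithms are the default throughout: the published coefficient
tables reproduce every quoted percentage only under base 10 with
probabilities in percent.  Natural logarithms are supported via
``log_base="e"`` for completeness, and :func:`convert_log_base` moves a
coefficient pair between bases (the exponent is base-invariant; only the
intercept rescales).

The law can also be assembled from its mechanistic components: a
proportionality ``alpha`` between probability and the number of diseased
ventricular fibers, an exponent ``beta``, and a proportionality ``gamma``
between diseased fibers and ST deviation.  The composite intercept is
``delta = log(alpha) + beta * log(gamma)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import (
    DegenerateCurveError,
    DomainError,
    ProbabilityOverflowWarning,
    ValidationError,
)

__all__ = [
    "AllometricCoefficients",
    "AllometricComponents",
    "predict",
    "invert",
    "components_to_coefficients",
    "convert_log_base",
]

LogBase = Union[int, float, str]


def _normalize_base(log_base: LogBase) -> float:
    """Map the user-facing ``log_base`` argument (10, "10", "e", math.e)
    to a float base."""
    if isinstance(log_base, str):
        token = log_base.strip().lower()
        if token == "e":
            return math.e
        if token == "10":
            return 10.0
        raise ValidationError(f"unsupported log base: {log_base!r} (use 10 or 'e')")
    base = float(log_base)
    if base <= 0 or base == 1.0:
        raise ValidationError(f"log base must be positive and != 1, got {base}")
    return base


@dataclass(frozen=True)
class AllometricCoefficients:
    """One fitted VF-probability curve: slope and intercept in log-log space.

    Parameters
    ----------
    beta
        Allometric exponent (slope of the log-log line); dimensionless.
    delta
        Intercept of the log-log line; equals the log of the probability
        (in percent) at 1 mm ST deviation.
    follow_up_months
        Optional time horizon the curve describes, in months.
    label
        Optional free-text study identifier.
    """

    beta: float
    delta: float
    follow_up_months: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta) and math.isfinite(self.delta)):
            raise ValidationError(
                f"coefficients must be finite, got beta={self.beta}, delta={self.delta}"
            )
        if self.follow_up_months is not None and not self.follow_up_months > 0:
            raise ValidationError(
                f"follow_up_months must be > 0, got {self.follow_up_months}"
            )


@dataclass(frozen=True)
class AllometricComponents:
    """Mechanistic decomposition of one curve.

    ``alpha`` scales probability with the number of diseased fibers,
    ``beta`` is the exponent, and ``gamma`` converts ST deviation (mm) into
    diseased-fiber count.  The fiber count itself is latent: it only ever
    appears as the product ``gamma * st``.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise DomainError(f"alpha must be > 0, got {self.alpha}")
        if not self.gamma > 0:
            raise DomainError(f"gamma must be > 0, got {self.gamma}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"beta must be finite, got {self.beta}")


def predict(
    coeffs: AllometricCoefficients,
    st_mm,
    log_base: LogBase = 10,
):
    """Evaluate the VF probability (percent) at one or more ST deviations.

    Computes ``base ** (delta + beta * log_base(st_mm))``.  Strictly
    increasing in ``st_mm`` when ``beta > 0``.  Being an extrapolating power
    law the result may mathematically exceed 100%; that case emits a
    :class:`ProbabilityOverflowWarning` rather than an error.

    Parameters
    ----------
    coeffs
        The curve to evaluate.
    st_mm
        Positive ST deviation(s) in mm; scalar or array-like.
    log_base
        10 (default) or "e".

    Returns
    -------
    float or ndarray
        Probability in percent, same shape as ``st_mm``.
    """
    base = _normalize_base(log_base)
    st = np.asarray(st_mm, dtype=float)
    if np.any(~np.isfinite(st)) or np.any(st <= 0):
        raise DomainError("st_mm must be finite and > 0")
    log_st = np.log(st) / np.log(base)
    prob = base ** (coeffs.delta + coeffs.beta * log_st)
    if np.any(prob > 100.0):
        warnings.warn(
            "predicted probability exceeds 100%; the power law is "
            "extrapolating beyond the probability scale",
            ProbabilityOverflowWarning,
            stacklevel=2,
        )
    if np.isscalar(st_mm) or np.ndim(st_mm) == 0:
        return float(prob)
    return prob


def invert(
    coeffs: AllometricCoefficients,
    probability_percent,
    log_base: LogBase = 10,
):
    """ST deviation (mm) at which the curve reaches a given probability.

    Algebraic inverse of :func:`predict`:
    ``base ** ((log_base(p) - delta) / beta)``.
    """
    base = _normalize_base(log_base)
    if coeffs.beta == 0:
        raise DegenerateCurveError("cannot invert a flat curve (beta = 0)")
    p = np.asarray(probability_percent, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0):
        raise DomainError("probability_percent must be finite and > 0")
    log_p = np.log(p) / np.log(base)
    st = base ** ((log_p - coeffs.delta) / coeffs.beta)
    if np.isscalar(probability_percent) or np.ndim(probability_percent) == 0:
        return float(st)
    return st


def components_to_coefficients(
    comp: AllometricComponents, log_base: LogBase = 10
) -> AllometricCoefficients:
    """Collapse (alpha, beta, gamma) into a (beta, delta) pair.

    ``delta = log(alpha) + beta * log(gamma)`` in the chosen base, so that
    ``predict`` on the result equals ``alpha * (gamma * st) ** beta``
    for every st > 0.
    """
    base = _normalize_base(log_base)
    log = lambda x: math.log(x) / math.log(base)  # noqa: E731
    return AllometricCoefficients(
        beta=comp.beta,
        delta=log(comp.alpha) + comp.beta * log(comp.gamma),
    )


def convert_log_base(
    coeffs: AllometricCoefficients,
    from_base: LogBase = 10,
    to_base: LogBase = "e",
) -> AllometricCoefficients:
    """Re-express a coefficient pair in another logarithm base.

    The exponent is base-invariant; the intercept rescales by
    ``log(from_base) / log(to_base)``.  Predictions are identical in
    either representation.
    """
    b_from = _normalize_base(from_base)
    b_to = _normalize_base(to_base)
    return AllometricCoefficients(
        beta=coeffs.beta,
        delta=coeffs.delta * math.log(b_from) / math.log(b_to),
        follow_up_months=coeffs.follow_up_months,
        label=coeffs.label,
    )
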