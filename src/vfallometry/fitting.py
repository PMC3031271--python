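"""Curve resampling and log-log regression.

The estimation pipeline works on sparse "study curves" — a handful of
(ST deviation, event probability) points per cohort and follow-up window,
typically three bins at 0.5, 1 and 2 mm.  Two steps turn such a curve into
allometric coefficients:

1. :func:`resample_quadratic` densifies the curve on a regular grid
   (default 0.5-2.0 mm in steps of 0.025 mm, 61 points) by piecewise
   quadratic interpolation: each grid value comes from the parabola through
   the three input knots nearest to it.  With exactly three input points
   this is the unique interpolating parabola.
2. :func:`fit_allometric` runs ordinary least squares of log(probability)
   on log(ST) over the (resampled) points, returning the slope as beta, the
   intercept as delta, and the adjusted r-square
   ``1 - (1 - r^2) * (n - 1) / (n - 2)`` for the two fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCurveError,
    DomainError,
    ExtrapolationError,
    InsufficientDataError,
    ValidationError,
)
from .model import AllometricCoefficients, LogBase, _normalize_base

__all__ = [
    "StudyCurve",
    "FitResult",
    "make_grid",
    "resample_quadratic",
    "fit_allometric",
    "DEFAULT_RANGE_MM",
    "DEFAULT_STEP_MM",
]

DEFAULT_RANGE_MM: tuple[float, float] = (0.5, 2.0)
DEFAULT_STEP_MM: float = 0.025


@dataclass(frozen=True)
class StudyCurve:
    """Observed event probabilities across ST-deviation bins.

    ``st_mm`` must be strictly increasing and positive; probabilities are
    percentages in (0, 100].  Zero probabilities are rejected because the
    log-log fit cannot take their logarithm.
    """

    st_mm: np.ndarray
    probability_percent: np.ndarray
    label: str = ""
    follow_up_months: float | None = None

    def __post_init__(self) -> None:
        st = np.atleast_1d(np.asarray(self.st_mm, dtype=float))
        prob = np.atleast_1d(np.asarray(self.probability_percent, dtype=float))
        object.__setattr__(self, "st_mm", st)
        object.__setattr__(self, "probability_percent", prob)
        if st.shape != prob.shape or st.ndim != 1:
            raise ValidationError("st_mm and probability_percent must be 1-D and equal length")
        if len(st) < 2:
            raise ValidationError("a study curve needs at least 2 points")
        if np.any(~np.isfinite(st)) or np.any(st <= 0):
            raise ValidationError("st_mm values must be finite and > 0")
        if np.any(np.diff(st) <= 0):
            raise ValidationError("st_mm values must be strictly increasing")
        if np.any(~np.isfinite(prob)) or np.any(prob <= 0) or np.any(prob > 100):
            raise ValidationError("probabilities must lie in (0, 100] percent")
        if self.follow_up_months is not None and not self.follow_up_months > 0:
            raise ValidationError("follow_up_months must be > 0")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.st_mm.tolist(), self.probability_percent.tolist()))

    def __len__(self) -> int:
        return len(self.st_mm)


@dataclass(frozen=True)
class FitResult:
    """Coefficients plus goodness-of-fit and fit-window metadata."""

    coefficients: AllometricCoefficients
    adjusted_r_square: float
    n_points: int
    fit_range_mm: tuple[float, float]
    step_mm: float | None = None
    log_base: LogBase = 10

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("a two-parameter fit needs at least 3 points")
        if self.adjusted_r_square > 1 + 1e-12:
            raise ValidationError("adjusted r-square cannot exceed 1")


def make_grid(range_mm: Sequence[float], step_mm: float) -> np.ndarray:
    """Regular inclusive grid over ``range_mm`` with the given step.

    The point count is computed as ``round((high - low) / step) + 1`` so the
    endpoints are hit exactly without floating accumulation.
    """
    low, high = float(range_mm[0]), float(range_mm[1])
    if not (low > 0 and high > low):
        raise ValidationError(f"invalid range: ({low}, {high})")
    if not step_mm > 0:
        raise ValidationError(f"step_mm must be > 0, got {step_mm}")
    n = int(round((high - low) / step_mm)) + 1
    return np.linspace(low, high, n)


def _quadratic_through(x_knots: np.ndarray, y_knots: np.ndarray, x: float) -> float:
    """Evaluate at ``x`` the parabola through three (x, y) knots
    (direct Vandermonde solve; exact for quadratics)."""
    coef = np.linalg.solve(np.vander(x_knots, 3), y_knots)
    return float(np.polyval(coef, x))


def resample_quadratic(
    curve: StudyCurve,
    range_mm: Sequence[float] = DEFAULT_RANGE_MM,
    step_mm: float = DEFAULT_STEP_MM,
) -> StudyCurve:
    """Resample a sparse curve on a regular grid by local quadratic
    interpolation.

    For each grid point the parabola through the three nearest input knots
    is evaluated (ties broken toward lower ST).  The interpolant passes
    through every original knot exactly, and reproduces any quadratic
    relationship exactly.  No extrapolation: the requested window must lie
    within the span of the data.
    """
    if len(curve) < 3:
        raise InsufficientDataError(
            f"quadratic resampling needs >= 3 points, got {len(curve)}"
        )
    grid = make_grid(range_mm, step_mm)
    lo_data, hi_data = curve.st_mm[0], curve.st_mm[-1]
    tol = 1e-12
    if grid[0] < lo_data - tol or grid[-1] > hi_data + tol:
        raise ExtrapolationError(
            f"requested range [{grid[0]}, {grid[-1]}] mm exceeds the data span "
            f"[{lo_data}, {hi_data}] mm"
        )
    st = curve.st_mm
    prob = curve.probability_percent
    values = np.empty_like(grid)
    for i, x in enumerate(grid):
        nearest = np.argsort(np.abs(st - x), kind="stable")[:3]
        nearest = np.sort(nearest)
        values[i] = _quadratic_through(st[nearest], prob[nearest], x)
    return StudyCurve(
        st_mm=grid,
        probability_percent=values,
        label=curve.label,
        follow_up_months=curve.follow_up_months,
    )


def fit_allometric(
    curve: StudyCurve,
    log_base: LogBase = 10,
    resample: bool = True,
    range_mm: Sequence[float] = DEFAULT_RANGE_MM,
    step_mm: float = DEFAULT_STEP_MM,
) -> FitResult:
    """Fit the allometric law by linear regression in log-log space.

    With ``resample=True`` (default) the curve is first densified by
    :func:`resample_quadratic` over ``range_mm``; the regression then runs
    on the gridded points.  Returns slope as beta, intercept as delta, and
    the two-parameter adjusted r-square.
    """
    base = _normalize_base(log_base)
    if resample:
        curve = resample_quadratic(curve, range_mm=range_mm, step_mm=step_mm)
    st = curve.st_mm
    prob = curve.probability_percent
    if np.any(prob <= 0):
        raise DomainError("all probabilities must be > 0 to take logarithms")
    n = len(st)
    if n < 3:
        raise InsufficientDataError(f"log-log fit needs >= 3 points, got {n}")
    if np.ptp(st) == 0:
        raise DegenerateCurveError("all ST values identical; design is singular")
    x = np.log(st) / np.log(base)
    y = np.log(prob) / np.log(base)
    res = stats.linregress(x, y)
    # r^2 from residuals so a perfectly fitted flat line scores 1 (the
    # correlation form is 0/0 when y is constant)
    ss_res = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a y-variance at float-noise level means the data are constant and the
    # flat line fits them perfectly
    tiny = 1e-24 * n * max(1.0, float(np.abs(y).max())) ** 2
    r2 = 1.0 - ss_res / ss_tot if ss_tot > tiny else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    coeffs = AllometricCoefficients(
        beta=float(res.slope),
        delta=float(res.intercept),
        follow_up_months=curve.follow_up_months,
        label=curve.label or None,
    )
    return FitResult(
        coefficients=coeffs,
        adjusted_r_square=float(adj),
        n_points=n,
        fit_range_mm=(float(st[0]), float(st[-1])),
        step_mm=step_mm if resample else None,
        log_base=log_base,
    )
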