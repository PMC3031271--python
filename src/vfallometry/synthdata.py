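"""Synthetic study tables with the statistical structure the fit assumes.

The original per-bin event rates behind the fitted curves were never
published, so this module generates stand-ins: event probabilities that
follow a ground-truth allometric law across ST bins and follow-up windows,
observed with cohort noise.  Two noise models are provided:

* ``binomial`` (default) — each bin observes ``100 * k / n`` with
  ``k ~ Binomial(n = cohort_size, p = truth / 100)``.  This mirrors how the
  source trials report event proportions among cohorts of stated sizes.
* ``lognormal`` — log10 of the true probability is perturbed by centred
  Gaussian noise of configurable SD; useful for regression-theory tests
  (sigma = 0 gives exact, noise-free curves).

A binomial draw can produce zero events, whose log the fit cannot take;
such a bin is redrawn once and, if still zero, dropped with a warning.

:func:`recovery_experiment` wraps the full generate-then-fit loop and
summarises the bias, SD and RMSE of the recovered coefficients per
follow-up window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import AllometryError, ValidationError
from .fitting import (
    DEFAULT_RANGE_MM,
    DEFAULT_STEP_MM,
    StudyCurve,
    fit_allometric,
)
from .model import (
    AllometricCoefficients,
    AllometricComponents,
    components_to_coefficients,
    predict,
)

__all__ = [
    "SyntheticStudyConfig",
    "paper_truth",
    "generate_study",
    "recovery_experiment",
    "DEFAULT_ST_BINS_MM",
    "DEFAULT_FOLLOW_UP_MONTHS",
    "DEFAULT_COHORT_SIZE",
]

#: ST subclassification used by the source cohorts (the open ">= 2 mm" bin
#: is represented by its nominal 2 mm value, as the fits themselves do).
DEFAULT_ST_BINS_MM: tuple[float, ...] = (0.5, 1.0, 2.0)
DEFAULT_FOLLOW_UP_MONTHS: tuple[float, ...] = (1.0, 6.0, 12.0, 48.0)
#: Patients per ST bin: roughly the largest source cohort (~6300 evaluated
#: patients) split equally across the three bins.
DEFAULT_COHORT_SIZE: int = 2000

Truth = Union[
    AllometricCoefficients,
    AllometricComponents,
    Mapping[float, Union[AllometricCoefficients, AllometricComponents]],
    None,
]


def paper_truth() -> dict[float, AllometricCoefficients]:
    """Published ground-truth laws per follow-up window: the derived mean
    curves at 1 and 6 months and the long-horizon curves at 12 and 48
    months."""
    from .io import load_coefficient_table

    table = load_coefficient_table()
    return {
        1.0: table.get("Mean PARAGON-A & GUSTO-IIB", 1),
        6.0: table.get("Mean PARAGON-A & GUSTO-IIB", 6),
        12.0: table.get("Hyde", 12),
        48.0: table.get("Hyde", 48),
    }


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Ground-truth law, ST bins, cohort sizes, windows and seed.

    ``truth`` may be a single coefficient pair or component triple (applied
    to every follow-up window), a mapping from window to law, or None for
    the published defaults.  ``noise_model`` is "binomial" or "lognormal";
    ``sigma_log10`` only applies to the latter.
    """

    truth: Truth = None
    st_bins_mm: tuple[float, ...] = DEFAULT_ST_BINS_MM
    follow_up_months: tuple[float, ...] = DEFAULT_FOLLOW_UP_MONTHS
    cohort_size_per_bin: int = DEFAULT_COHORT_SIZE
    seed: int = 0
    noise_model: str = "binomial"
    sigma_log10: float = 0.02

    def __post_init__(self) -> None:
        if self.cohort_size_per_bin < 1:
            raise ValidationError("cohort_size_per_bin must be >= 1")
        if any(b <= 0 for b in self.st_bins_mm):
            raise ValidationError("all ST bins must be > 0")
        if any(m <= 0 for m in self.follow_up_months):
            raise ValidationError("all follow-up windows must be > 0")
        if self.noise_model not in ("binomial", "lognormal"):
            raise ValidationError(f"unknown noise model: {self.noise_model!r}")
        if self.sigma_log10 < 0:
            raise ValidationError("sigma_log10 must be >= 0")

    def truth_by_window(self) -> dict[float, AllometricCoefficients]:
        """Normalise ``truth`` to a window -> coefficients mapping."""
        truth = self.truth if self.truth is not None else paper_truth()
        if isinstance(truth, AllometricComponents):
            truth = components_to_coefficients(truth)
        if isinstance(truth, AllometricCoefficients):
            return {float(m): truth for m in self.follow_up_months}
        out: dict[float, AllometricCoefficients] = {}
        for m in self.follow_up_months:
            try:
                law = truth[float(m)] if float(m) in truth else truth[m]
            except (KeyError, TypeError):
                raise ValidationError(
                    f"no ground-truth law for follow-up window {m} months"
                ) from None
            if isinstance(law, AllometricComponents):
                law = components_to_coefficients(law)
            out[float(m)] = law
        return out


def _observe_bin(
    rng: np.random.Generator, truth_percent: float, config: SyntheticStudyConfig
) -> float:
    """One noisy observation of a bin's event probability, in percent."""
    if config.noise_model == "binomial":
        n = config.cohort_size_per_bin
        k = rng.binomial(n, truth_percent / 100.0)
        return 100.0 * k / n
    # lognormal: multiplicative noise on the probability
    obs = 10.0 ** (np.log10(truth_percent) + rng.normal(0.0, config.sigma_log10))
    return min(float(obs), 100.0)


def generate_study(config: SyntheticStudyConfig) -> list[StudyCurve]:
    """Generate one synthetic StudyCurve per follow-up window.

    Deterministic given the seed.  Bins observing zero events are redrawn
    once; a second zero drops the bin with a warning (its log does not
    exist, so the fit could not use it anyway).
    """
    truth = config.truth_by_window()
    rng = np.random.default_rng(config.seed)
    bins = np.asarray(config.st_bins_mm, dtype=float)
    curves: list[StudyCurve] = []
    for months in config.follow_up_months:
        law = truth[float(months)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # truth > 100 is vetted below, not warned
            truth_percent = np.atleast_1d(predict(law, bins, log_base=10))
        if np.any(truth_percent > 100.0):
            raise ValidationError(
                f"ground-truth probability exceeds 100% at window {months} months"
            )
        kept_st: list[float] = []
        kept_prob: list[float] = []
        for st, p_true in zip(bins, truth_percent):
            obs = _observe_bin(rng, float(p_true), config)
            if obs == 0.0:
                obs = _observe_bin(rng, float(p_true), config)
            if obs == 0.0:
                warnings.warn(
                    f"bin {st} mm at {months} months observed zero events twice; "
                    "excluded from the synthetic curve",
                    stacklevel=2,
                )
                continue
            kept_st.append(float(st))
            kept_prob.append(obs)
        curves.append(
            StudyCurve(
                st_mm=kept_st,
                probability_percent=kept_prob,
                label=f"synthetic-{months:g}mo",
                follow_up_months=float(months),
            )
        )
    return curves


def recovery_experiment(
    config: SyntheticStudyConfig,
    n_replicates: int,
    log_base=10,
    resample: bool = True,
    range_mm: Sequence[float] = DEFAULT_RANGE_MM,
    step_mm: float = DEFAULT_STEP_MM,
) -> pd.DataFrame:
    """Generate-and-refit simulation summarising coefficient recovery.

    Runs ``n_replicates`` independent studies (replicate seeds are spawned
    deterministically from ``config.seed``), fits each follow-up window's
    curve, and reports per window the bias, sample SD and RMSE of the
    fitted beta and delta against the ground truth.  Replicates whose fit
    fails (e.g. after zero-event bin exclusion leaves too few points) are
    counted in ``n_failed`` and excluded from the moments.

    Returns
    -------
    pandas.DataFrame
        One row per follow-up window with columns ``follow_up_months``,
        ``truth_beta``, ``truth_delta``, ``bias_beta``, ``sd_beta``,
        ``rmse_beta``, ``bias_delta``, ``sd_delta``, ``rmse_delta``,
        ``n_ok``, ``n_failed``.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    truth = config.truth_by_window()
    seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (2**31)
    estimates: dict[float, list[tuple[float, float]]] = {
        float(m): [] for m in config.follow_up_months
    }
    failures: dict[float, int] = {float(m): 0 for m in config.follow_up_months}
    for rep_seed in seeds:
        rep_config = replace(config, seed=int(rep_seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = generate_study(rep_config)
        for curve in curves:
            months = float(curve.follow_up_months)
            try:
                fit = fit_allometric(
                    curve,
                    log_base=log_base,
                    resample=resample,
                    range_mm=range_mm,
                    step_mm=step_mm,
                )
            except AllometryError:
                failures[months] += 1
                continue
            estimates[months].append((fit.coefficients.beta, fit.coefficients.delta))
    rows = []
    for months in config.follow_up_months:
        months = float(months)
        law = truth[months]
        est = np.asarray(estimates[months], dtype=float)
        row: dict[str, float] = {
            "follow_up_months": months,
            "truth_beta": law.beta,
            "truth_delta": law.delta,
            "n_ok": len(est),
            "n_failed": failures[months],
        }
        for j, name in enumerate(("beta", "delta")):
            if len(est) >= 2:
                err = est[:, j] - (law.beta if name == "beta" else law.delta)
                row[f"bias_{name}"] = float(err.mean())
                row[f"sd_{name}"] = float(err.std(ddof=1))
                row[f"rmse_{name}"] = float(np.sqrt(np.mean(err**2)))
            else:
                row[f"bias_{name}"] = np.nan
                row[f"sd_{name}"] = np.nan
                row[f"rmse_{name}"] = np.nan
        rows.append(row)
    columns = [
        "follow_up_months",
        "truth_beta",
        "truth_delta",
        "bias_beta",
        "sd_beta",
        "rmse_beta",
        "bias_delta",
        "sd_delta",
        "rmse_delta",
        "n_ok",
        "n_failed",
    ]
    return pd.DataFrame(rows, columns=columns)
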