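"""Re-derive every published headline number from the coefficient fixture.

:func:`reproduce_paper` recomputes, from the packaged coefficient table
alone, the twelve quantities quoted alongside the fitted curve family:

* eight single-curve predictions (the 2 mm range endpoints at 1 and 48
  months, and the six study-curve values at 1.5 mm);
* the slope and intercept of the probability-space mean of the two 1-month
  study curves after log-log refit, and the slope of the 6-month pair;
* the SEM prediction band across all six study curves at 1.5 mm.

Each row carries the computed value, the printed value, and a match flag
applied after the printed rounding (integer percent for probabilities, two
decimals for coefficients).  Running with ``log_base="e"`` documents that
natural logarithms do **not** reproduce the printed predictions — the
published numbers are base-10 quantities.

Study-level and overall-average coefficient rows are inputs, not outputs:
the per-bin event rates they were fitted to were never published, so those
fits cannot be recomputed and are deliberately absent from this report.
"""

from __future__ import annotations

import pandas as pd

from .aggregation import mean_curve_refit, overall_average_band
from .io import load_coefficient_table
from .model import LogBase, predict

__all__ = ["reproduce_paper"]


def _round_int(x: float) -> int:
    return int(round(x))


def reproduce_paper(log_base: LogBase = 10) -> pd.DataFrame:
    """Recompute the published headline quantities from the fixture.

    Returns a DataFrame with columns ``quantity``, ``computed``,
    ``printed``, ``match``.  Deterministic; no randomness anywhere.
    """
    table = load_coefficient_table()
    paragon1 = table.get("PARAGON-A", 1)
    paragon6 = table.get("PARAGON-A", 6)
    gusto1 = table.get("GUSTO-IIB", 1)
    gusto6 = table.get("GUSTO-IIB", 6)
    hyde12 = table.get("Hyde", 12)
    hyde48 = table.get("Hyde", 48)
    six = table.study_curves()

    rows: list[dict] = []

    def add_prediction(quantity, coeffs, st, printed, upper_bound=False):
        value = predict(coeffs, st, log_base=log_base)
        if upper_bound:
            # quoted as "slightly below" the printed percentage
            match = value <= printed
            computed = round(value, 2)
        else:
            match = _round_int(value) == printed
            computed = _round_int(value)
        rows.append(
            {"quantity": quantity, "computed": computed, "printed": printed, "match": match}
        )

    add_prediction("VF probability at 2.0 mm, 1 month, GUSTO-IIb [%]", gusto1, 2.0, 13)
    add_prediction("VF probability at 2.0 mm, 48 months [%]", hyde48, 2.0, 86)
    add_prediction(
        "VF probability at 1.5 mm, 1 month, GUSTO-IIb [%] (upper bound)",
        gusto1,
        1.5,
        11,
        upper_bound=True,
    )
    add_prediction("VF probability at 1.5 mm, 1 month, PARAGON-A [%]", paragon1, 1.5, 15)
    add_prediction("VF probability at 1.5 mm, 6 months, GUSTO-IIb [%]", gusto6, 1.5, 15)
    add_prediction("VF probability at 1.5 mm, 6 months, PARAGON-A [%]", paragon6, 1.5, 20)
    add_prediction("VF probability at 1.5 mm, 12 months [%]", hyde12, 1.5, 45)
    add_prediction("VF probability at 1.5 mm, 48 months [%]", hyde48, 1.5, 75)

    # Mean-row coefficients: probability-space average + log-log refit.
    # The refit itself is a base-10 construction; under base e the
    # comparison is made against the base-10 printed values and fails,
    # which is the point of the log-base documentation run.
    fit1, _ = mean_curve_refit([paragon1, gusto1])
    fit6, _ = mean_curve_refit([paragon6, gusto6])
    if str(log_base).strip().lower() == "e":
        import math

        scale = math.log(10.0)  # present the base-e intercept as-is
        beta1, delta1 = fit1.coefficients.beta, fit1.coefficients.delta * scale
        beta6 = fit6.coefficients.beta
    else:
        beta1, delta1 = fit1.coefficients.beta, fit1.coefficients.delta
        beta6 = fit6.coefficients.beta
    for quantity, computed, printed in [
        ("mean 1-month curve: refit slope beta", round(beta1, 2), 0.50),
        ("mean 1-month curve: refit intercept delta", round(delta1, 2), 1.01),
        ("mean 6-month curve: refit slope beta", round(beta6, 2), 0.49),
    ]:
        rows.append(
            {
                "quantity": quantity,
                "computed": computed,
                "printed": printed,
                "match": computed == printed,
            }
        )

    # Overall SEM band at 1.5 mm across the six study curves.
    band = overall_average_band(six)
    low, _, high = band.at(1.5)
    low_i, high_i = _round_int(low), _round_int(high)
    rows.append(
        {
            "quantity": "SEM band at 1.5 mm across six curves [%]",
            "computed": f"{low_i}-{high_i}",
            "printed": "17-32",
            "match": (low_i, high_i) == (17, 32),
        }
    )
    return pd.DataFrame(rows, columns=["quantity", "computed", "printed", "match"])
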