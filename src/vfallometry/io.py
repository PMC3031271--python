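"""Delimited-text I/O for coefficient tables and study curves.

File dialect: comma-separated, UTF-8, period decimal separator, mandatory
header row.

The package ships the published coefficient table as a fixture
(``data/table1_coefficients.csv``): nine (label, follow-up, beta, delta,
adjusted r-square) rows — four study-level curves at 1 and 6 months, two
longer-horizon curves at 12 and 48 months, two derived "mean" rows, and one
overall "Average curve" row whose coefficients are consumed as given (the
raw per-bin event rates behind the study fits were never published, so
those rows cannot be recomputed from available inputs).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from .errors import ParseError, ValidationError
from .fitting import StudyCurve
from .model import AllometricCoefficients

__all__ = [
    "CoefficientRow",
    "CoefficientTable",
    "load_coefficient_table",
    "write_coefficient_table",
    "read_study_curve",
    "write_study_curve",
    "STUDY_CURVE_KEYS",
]

_COEFF_HEADER = ["label", "follow_up_months", "beta", "delta", "adjusted_r_square"]
_CURVE_HEADER = ["st_mm", "probability_percent"]

#: (label, follow_up_months) keys of the six study-level curves in the
#: packaged fixture, in canonical order.  The "Mean" and "Average curve"
#: rows are derived quantities and deliberately not listed here.
STUDY_CURVE_KEYS: tuple[tuple[str, float], ...] = (
    ("PARAGON-A", 1),
    ("PARAGON-A", 6),
    ("GUSTO-IIB", 1),
    ("GUSTO-IIB", 6),
    ("Hyde", 12),
    ("Hyde", 48),
)


@dataclass(frozen=True)
class CoefficientRow:
    label: str
    follow_up_months: float | None
    beta: float
    delta: float
    adjusted_r_square: float | None = None

    def to_coefficients(self) -> AllometricCoefficients:
        return AllometricCoefficients(
            beta=self.beta,
            delta=self.delta,
            follow_up_months=self.follow_up_months,
            label=self.label,
        )


@dataclass(frozen=True)
class CoefficientTable:
    """Validated set of coefficient rows, keyed by (label, follow-up)."""

    rows: tuple[CoefficientRow, ...]

    def __post_init__(self) -> None:
        keys = [(r.label, r.follow_up_months) for r in self.rows]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (label, follow_up) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, label: str, follow_up_months: float | None = None) -> AllometricCoefficients:
        for r in self.rows:
            if r.label == label and (
                follow_up_months is None or r.follow_up_months == follow_up_months
            ):
                return r.to_coefficients()
        raise KeyError(f"no row with label={label!r}, follow_up={follow_up_months!r}")

    def study_curves(self) -> list[AllometricCoefficients]:
        """The six study-level curves, in canonical order."""
        return [self.get(label, months) for label, months in STUDY_CURVE_KEYS]


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: cannot parse {what} from {token!r}") from None


def load_coefficient_table(path: str | Path | None = None) -> CoefficientTable:
    """Read a coefficient table from ``path``, or the packaged fixture when
    ``path`` is None.

    Raises :class:`ParseError` (with line number) on malformed rows and
    :class:`ValidationError` on duplicate keys.
    """
    if path is None:
        source = resources.files("vfallometry.data").joinpath("table1_coefficients.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    reader = csv.reader(text.splitlines())
    rows: list[CoefficientRow] = []
    header: list[str] | None = None
    for lineno, record in enumerate(reader, start=1):
        if not record or all(not cell.strip() for cell in record):
            continue
        if header is None:
            header = [cell.strip() for cell in record]
            if header[: len(_COEFF_HEADER) - 1] != _COEFF_HEADER[:4]:
                raise ParseError(
                    f"line {lineno}: expected header {','.join(_COEFF_HEADER)}, "
                    f"got {','.join(header)}"
                )
            continue
        if len(record) < 4:
            raise ParseError(f"line {lineno}: expected >= 4 fields, got {len(record)}")
        label = record[0].strip()
        if not label:
            raise ParseError(f"line {lineno}: empty label")
        months_token = record[1].strip()
        months = _parse_float(months_token, "follow_up_months", lineno) if months_token else None
        beta = _parse_float(record[2].strip(), "beta", lineno)
        delta = _parse_float(record[3].strip(), "delta", lineno)
        r2 = None
        if len(record) > 4 and record[4].strip():
            r2 = _parse_float(record[4].strip(), "adjusted_r_square", lineno)
        rows.append(CoefficientRow(label, months, beta, delta, r2))
    if header is None:
        raise ParseError("empty file: no header row found")
    return CoefficientTable(rows=tuple(rows))


def write_coefficient_table(table: CoefficientTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COEFF_HEADER)
        for r in table.rows:
            writer.writerow(
                [
                    r.label,
                    "" if r.follow_up_months is None else f"{r.follow_up_months:g}",
                    repr(r.beta),
                    repr(r.delta),
                    "" if r.adjusted_r_square is None else repr(r.adjusted_r_square),
                ]
            )


def read_study_curve(
    path: str | Path,
    label: str = "",
    follow_up_months: float | None = None,
) -> StudyCurve:
    """Read one (st_mm, probability_percent) curve from a CSV file.

    Metadata (label, follow-up) is not stored in the file; pass it here.
    """
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.reader(text.splitlines())
    st: list[float] = []
    prob: list[float] = []
    header: list[str] | None = None
    for lineno, record in enumerate(reader, start=1):
        if not record or all(not cell.strip() for cell in record):
            continue
        if header is None:
            header = [cell.strip() for cell in record]
            if header[:2] != _CURVE_HEADER:
                raise ParseError(
                    f"line {lineno}: expected header {','.join(_CURVE_HEADER)}, "
                    f"got {','.join(header)}"
                )
            continue
        if len(record) < 2:
            raise ParseError(f"line {lineno}: expected 2 fields, got {len(record)}")
        st.append(_parse_float(record[0].strip(), "st_mm", lineno))
        prob.append(_parse_float(record[1].strip(), "probability_percent", lineno))
    if header is None:
        raise ParseError("empty file: no header row found")
    if not st:
        raise ParseError("no data rows found")
    return StudyCurve(
        st_mm=st, probability_percent=prob, label=label, follow_up_months=follow_up_months
    )


def write_study_curve(curve: StudyCurve, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CURVE_HEADER)
        for s, p in curve.points:
            writer.writerow([repr(s), repr(p)])
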