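import numpy as np
import pytest

from vfallometry import load_coefficient_table


@pytest.fixture(scope="session")
def table():
    """The packaged published coefficient table."""
    return load_coefficient_table()


@pytest.fixture(scope="session")
def gusto1(table):
    return table.get("GUSTO-IIB", 1)


@pytest.fixture(scope="session")
def hyde48(table):
    return table.get("Hyde", 48)


@pytest.fixture(scope="session")
def six_study_curves(table):
    return table.study_curves()


def ols_normal_equations(x, y):
    """Independent OLS oracle: explicit normal-equations solve for
    (slope, intercept) of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xtx = np.array([[np.sum(x * x), np.sum(x)], [np.sum(x), n]])
    xty = np.array([np.sum(x * y), np.sum(y)])
    slope, intercept = np.linalg.solve(xtx, xty)
    return slope, intercept


@pytest.fixture(scope="session")
def normal_equations_oracle():
    return ols_normal_equations
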