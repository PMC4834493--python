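import numpy as np
import pytest

from flipbind.landscape import (
    asymmetric_double_well,
    harmonic_well,
    src_imatinib_profile,
    symmetric_double_well,
)


@pytest.fixture(scope="session")
def profile():
    """Desk-scale binding profile (7 kcal/mol main barrier)."""
    return src_imatinib_profile()


@pytest.fixture(scope="session")
def full_scale_profile():
    """Full-scale binding profile (16.5 kcal/mol main barrier)."""
    return src_imatinib_profile(full_scale=True)


@pytest.fixture(scope="session")
def double_well():
    return asymmetric_double_well()


@pytest.fixture(scope="session")
def sym_well():
    return symmetric_double_well(barrier=2.0)


@pytest.fixture(scope="session")
def harmonic():
    return harmonic_well(k=2.0)


def quadrature_dg(land, boundary, temperature=300.0):
    """Oracle: basin free-energy difference (right minus left) by direct
    Boltzmann quadrature of the analytic potential."""
    from flipbind.constants import kt

    lo, hi = land.domain
    g = np.arange(lo - 1.0, hi + 1.0, 0.002)
    u = land.potential(g)
    u = u - u.min()
    w = np.exp(-u / kt(temperature))
    left = np.trapezoid(w[g < boundary], g[g < boundary])
    right = np.trapezoid(w[g >= boundary], g[g >= boundary])
    return -kt(temperature) * np.log(right / left)
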