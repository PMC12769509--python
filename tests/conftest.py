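import numpy as np
import pytest

from strdyn.motifs import canonical_label
from strdyn.rates import (
    RateCurve,
    SubstitutionContextRates,
    default_empirical_curve,
    default_substitution_rates,
)


@pytest.fixture(scope="session")
def subst():
    return default_substitution_rates()


@pytest.fixture(scope="session")
def two_way_subst():
    # uniform two-way point mutation at the printed mono-A mu/nu
    return SubstitutionContextRates.two_way(a_to_b=7.74e-9, b_to_a=4.58e-9)


@pytest.fixture(scope="session")
def empirical():
    return default_empirical_curve()


@pytest.fixture(scope="session")
def class_a():
    return canonical_label("A")


@pytest.fixture
def zero_curve():
    z = np.zeros(81)
    return RateCurve(z.copy(), z.copy(), z.copy())


@pytest.fixture
def inflated_curve():
    """Strongly instability-biased rates for fast, well-populated dynamics."""
    L = np.arange(41, dtype=float)
    eps = 2e-5 * (L / 9) ** 1.6
    kap = 1.2e-5 * (L / 9) ** 2.0
    eps[0] = kap[0] = 0.0
    return RateCurve(eps, kap, eps / 50)


@pytest.fixture
def inflated_subst():
    return SubstitutionContextRates(
        4.6e-5, 7.7e-5, 2.7e-5, 4.4e-5, 3.8e-5, 6.2e-5, 1.4e-6, 4.4e-8, 2.8e-6
    )
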