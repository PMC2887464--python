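from fractions import Fraction

import pytest

from tetraseg import Assay, GeneticModel, ObservedCounts


@pytest.fixture(scope="session")
def six_candidates():
    from tetraseg import standard_candidates

    return standard_candidates(alpha=Fraction(1, 6))


@pytest.fixture()
def duplex_recessive():
    return GeneticModel.standard("duplex", "recessive", alpha=Fraction(1, 6))


@pytest.fixture()
def triplex_recessive():
    return GeneticModel.standard("triplex", "recessive", alpha=Fraction(1, 6))


@pytest.fixture(scope="session")
def screen_observations():
    """Observed counts of the six-model determination screen."""
    return (
        ObservedCounts(Assay.SEED_SET, 171, 507),
        ObservedCounts(Assay.PROGENY, 327, 25),
    )
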