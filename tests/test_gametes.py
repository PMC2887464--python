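"""Gamete-class frequencies, the enumeration oracle, and selection rules."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetraseg import (
    DominanceMode,
    GameteClassDistribution,
    ParentGenotype,
    SegregationRegime,
    SelectionModel,
    apply_female_selection,
    apply_male_selection,
    enumerate_gametes,
    gamete_frequencies,
)

ALPHAS = [Fraction(0), Fraction(1, 7), Fraction(1, 6)]

alpha_strategy = st.fractions(
    min_value=Fraction(0), max_value=Fraction(1, 6), max_denominator=1000
)


@pytest.mark.parametrize(
    "dosage, alpha, expected",
    [
        # classical 1:4:1 chromosomal segregation of a duplex heterozygote
        (2, Fraction(0), {0: Fraction(1, 6), 1: Fraction(4, 6), 2: Fraction(1, 6)}),
        # maximal double reduction shifts mass to the homozygous classes
        (2, Fraction(1, 6), {0: Fraction(2, 9), 1: Fraction(5, 9), 2: Fraction(2, 9)}),
        (0, Fraction(1, 6), {0: Fraction(1), 1: Fraction(0), 2: Fraction(0)}),
        (4, Fraction(1, 7), {0: Fraction(0), 1: Fraction(0), 2: Fraction(1)}),
    ],
)
def test_tetraploid_gamete_frequencies(dosage, alpha, expected):
    dist = gamete_frequencies(ParentGenotype(4, dosage), alpha)
    assert dict(dist.items()) == expected


def test_triplex_homozygous_gamete_fraction_is_13_24():
    """The fully mutant diploid gamete class of a triplex parent at maximal
    double reduction — the proliferating-FG fraction — is exactly 13/24."""
    dist = gamete_frequencies(ParentGenotype(4, 3), Fraction(1, 6))
    assert dist[2] == Fraction(13, 24)
    assert round(100 * float(dist[2])) == 54


def test_diploid_gametes_segregate_by_dosage():
    het = gamete_frequencies(ParentGenotype(2, 1), 0)
    assert dict(het.items()) == {0: Fraction(1, 2), 1: Fraction(1, 2)}
    wt = gamete_frequencies(ParentGenotype(2, 0), 0)
    assert dict(wt.items()) == {0: Fraction(1), 1: Fraction(0)}


@pytest.mark.parametrize("bad_alpha", [Fraction(-1, 10), Fraction(1, 5), 1])
def test_alpha_out_of_range_rejected(bad_alpha):
    with pytest.raises(ValueError):
        gamete_frequencies(ParentGenotype(4, 2), bad_alpha)


def test_diploid_parent_rejects_nonzero_alpha():
    with pytest.raises(ValueError):
        gamete_frequencies(ParentGenotype(2, 1), Fraction(1, 6))


@pytest.mark.parametrize("ploidy, dosage", [(3, 1), (6, 2), (4, 5), (4, -1)])
def test_invalid_parent_rejected(ploidy, dosage):
    with pytest.raises(ValueError):
        ParentGenotype(ploidy, dosage)


@pytest.mark.parametrize("dosage", range(5))
def test_oracle_equivalence(dosage):
    """The closed form agrees exactly with brute-force enumeration: alpha=0
    with chromosome-pair draws, alpha=1/7 with chromatid-pair draws."""
    parent = ParentGenotype(4, dosage)
    assert gamete_frequencies(parent, 0) == enumerate_gametes(
        parent, SegregationRegime.CHROMOSOMAL
    )
    assert gamete_frequencies(parent, Fraction(1, 7)) == enumerate_gametes(
        parent, SegregationRegime.RANDOM_CHROMATID
    )


def test_oracle_duplex_chromatid_values():
    dist = enumerate_gametes(ParentGenotype(4, 2), "random_chromatid")
    assert dict(dist.items()) == {
        0: Fraction(3, 14),
        1: Fraction(8, 14),
        2: Fraction(3, 14),
    }


@given(dosage=st.integers(0, 4), alpha=alpha_strategy)
@settings(derandomize=True, max_examples=200)
def test_frequencies_sum_to_one_and_swap_symmetry(dosage, alpha):
    dist = gamete_frequencies(ParentGenotype(4, dosage), alpha)
    assert sum(f for _, f in dist.items()) == 1
    mirrored = gamete_frequencies(ParentGenotype(4, 4 - dosage), alpha)
    assert dist.relabelled_swapped() == mirrored


@pytest.mark.parametrize("dosage", [1, 2, 3])
def test_double_reduction_monotonicity(dosage):
    """More double reduction means strictly more homozygous and strictly
    fewer heterozygous gametes."""
    grid = [Fraction(k, 60) for k in range(11)]  # 0 .. 1/6
    dists = [gamete_frequencies(ParentGenotype(4, dosage), a) for a in grid]
    for lo, hi in zip(dists, dists[1:]):
        assert hi[1] < lo[1]
        assert hi[0] + hi[2] > lo[0] + lo[2]


class TestSelection:
    def test_recessive_rule_structure(self):
        sel = SelectionModel.build("recessive")
        assert sel.female_aborting == {2}
        assert sel.male_weights == {
            0: Fraction(1),
            1: Fraction(1),
            2: Fraction(1, 10),
        }

    def test_dominant_rule_structure(self):
        sel = SelectionModel.build(DominanceMode.DOMINANT)
        assert sel.female_aborting == {1, 2}
        assert sel.male_weights[1] == Fraction(1, 10)

    def test_female_selection_duplex_recessive(self):
        dist = gamete_frequencies(ParentGenotype(4, 2), Fraction(1, 6))
        viable, abort = apply_female_selection(dist, SelectionModel.build("recessive"))
        assert abort == Fraction(2, 9)
        assert dict(viable.items()) == {0: Fraction(2, 7), 1: Fraction(5, 7)}

    def test_female_selection_simplex_dominant(self):
        dist = gamete_frequencies(ParentGenotype(4, 1), Fraction(1, 6))
        _, abort = apply_female_selection(dist, SelectionModel.build("dominant"))
        assert abort == Fraction(11, 24)

    def test_female_selection_degenerate(self):
        dist = gamete_frequencies(ParentGenotype(4, 4), 0)
        viable, abort = apply_female_selection(dist, SelectionModel.build("recessive"))
        assert viable is None and abort == 1

    def test_male_selection_duplex_recessive(self):
        dist = gamete_frequencies(ParentGenotype(4, 2), Fraction(1, 6))
        out = apply_male_selection(dist, SelectionModel.build("recessive"))
        # weights (1, 1, 1/10) on (2/9, 5/9, 2/9), renormalised
        assert dict(out.items()) == {
            0: Fraction(5, 18),
            1: Fraction(25, 36),
            2: Fraction(1, 36),
        }

    def test_male_selection_identity_with_unit_weights(self):
        dist = gamete_frequencies(ParentGenotype(4, 3), Fraction(1, 6))
        sel = SelectionModel.build("recessive", male_te=1)
        assert apply_male_selection(dist, sel) == dist

    def test_male_selection_triplex_dominant_class0_share(self):
        dist = gamete_frequencies(ParentGenotype(4, 3), Fraction(1, 6))
        out = apply_male_selection(dist, SelectionModel.build("dominant"))
        assert out[0] == Fraction(10, 33)

    def test_male_selection_degenerate(self):
        dist = gamete_frequencies(ParentGenotype(4, 4), 0)
        sel = SelectionModel.build("recessive", male_te=0)
        with pytest.raises(ValueError):
            apply_male_selection(dist, sel)

    @given(dosage=st.integers(0, 3), alpha=alpha_strategy)
    @settings(derandomize=True, max_examples=100)
    def test_female_selection_conserves_probability(self, dosage, alpha):
        dist = gamete_frequencies(ParentGenotype(4, dosage), alpha)
        viable, abort = apply_female_selection(dist, SelectionModel.build("recessive"))
        if viable is None:
            assert abort == 1
        else:
            total_viable = sum(f for _, f in viable.items())
            assert abort + (1 - abort) * total_viable == 1


def test_distribution_validates_sum_and_sign():
    with pytest.raises(ValueError):
        GameteClassDistribution({0: Fraction(1, 2), 1: Fraction(1, 3)})
    with pytest.raises(ValueError):
        GameteClassDistribution({0: Fraction(3, 2), 1: Fraction(-1, 2)})


def test_genotype_names_round_trip():
    for name in ("nulliplex", "simplex", "duplex", "triplex", "quadruplex"):
        assert ParentGenotype.from_name(name).name == name
    assert ParentGenotype.from_name("diploid_het") == ParentGenotype(2, 1)
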