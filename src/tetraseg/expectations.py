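"""Expected two-category counts for the three assays scored in a selfing test.

Given a parent genotype, a dominance/selection rule and a double-reduction
coefficient, this module predicts:

* **seed set** — infertile ovules : developing seeds.  Infertility is modelled
  purely as female-gametophyte abortion; pollen is treated as non-limiting, so
  male selection never reduces seed number.
* **progeny segregation** — resistant : sensitive seedlings on selection
  medium, where resistance marks inheritance of at least one copy of the
  (T-DNA-tagged) mutant allele.  A seedling is sensitive iff both its female
  and its male gamete carried zero mutant copies.
* **female-gametophyte (FG) phenotype** — proliferating : normal embryo sacs
  scored in cleared ovules.  Proliferating FGs are the fully mutant gamete
  class *before* selection, because doomed FGs are still visible and counted.

Expected counts are kept as exact Fractions; ``ExpectedCounts.ratio`` rounds
half-up for display, but goodness-of-fit statistics must consume the
unrounded values (see :mod:`tetraseg.inference`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from math import floor

from .gametes import (
    DEFAULT_MALE_TE,
    MAX_ALPHA,
    DominanceMode,
    FractionLike,
    GameteClassDistribution,
    ParentGenotype,
    SelectionModel,
    apply_female_selection,
    apply_male_selection,
    as_fraction,
    gamete_frequencies,
    validate_alpha,
)

__all__ = [
    "Assay",
    "GeneticModel",
    "ExpectedCounts",
    "standard_candidates",
    "expected_counts",
    "expected_seed_set",
    "expected_progeny",
    "expected_fg_phenotypes",
    "offspring_dosage_distribution",
    "triploid_recovery_probability",
    "round_half_up",
]


class Assay(str, Enum):
    SEED_SET = "seed_set"
    PROGENY = "progeny"
    FG_PHENOTYPE = "fg_phenotype"


#: Which count is category_a in each assay (category_b is the complement).
CATEGORY_LABELS = {
    Assay.SEED_SET: ("infertile", "developing"),
    Assay.PROGENY: ("resistant", "sensitive"),
    Assay.FG_PHENOTYPE: ("proliferating", "normal"),
}


def round_half_up(x: Fraction | float) -> int:
    """Round to the nearest integer with ties going up (display convention)."""
    f = as_fraction(x) if not isinstance(x, Fraction) else x
    return floor(f + Fraction(1, 2))


@dataclass(frozen=True)
class GeneticModel:
    """One candidate hypothesis: parent dosage x dominance rule x alpha."""

    parent: ParentGenotype
    selection: SelectionModel
    alpha: Fraction = MAX_ALPHA
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", validate_alpha(self.alpha))
        if not self.label:
            dr = "" if self.alpha else ", no DR"
            object.__setattr__(
                self,
                "label",
                f"{self.parent.name.capitalize()}, {self.selection.mode.value}{dr}",
            )

    @classmethod
    def standard(
        cls,
        genotype: str | ParentGenotype,
        mode: DominanceMode | str,
        alpha: FractionLike | float = MAX_ALPHA,
        male_te: FractionLike | float = DEFAULT_MALE_TE,
    ) -> "GeneticModel":
        """Convenience constructor from a genotype name and dominance mode."""
        parent = (
            genotype
            if isinstance(genotype, ParentGenotype)
            else ParentGenotype.from_name(genotype)
        )
        selection = SelectionModel.build(
            mode, gamete_classes=parent.gamete_classes, male_te=male_te
        )
        return cls(parent=parent, selection=selection, alpha=as_fraction(alpha))

    # -- cached gamete-pool views -------------------------------------------

    def gametes(self) -> GameteClassDistribution:
        """Pre-selection gamete-class distribution (both sexes)."""
        return gamete_frequencies(self.parent, self.alpha)

    def female_pool(self) -> tuple[GameteClassDistribution | None, Fraction]:
        return apply_female_selection(self.gametes(), self.selection)

    def male_pool(self) -> GameteClassDistribution:
        return apply_male_selection(self.gametes(), self.selection)


def standard_candidates(
    alpha: FractionLike | float = MAX_ALPHA,
    male_te: FractionLike | float = DEFAULT_MALE_TE,
) -> list[GeneticModel]:
    """The six canonical hypotheses for a tetraploid of unknown dosage:
    simplex/duplex/triplex x recessive/dominant."""
    return [
        GeneticModel.standard(g, m, alpha=alpha, male_te=male_te)
        for g in ("simplex", "duplex", "triplex")
        for m in (DominanceMode.RECESSIVE, DominanceMode.DOMINANT)
    ]


@dataclass(frozen=True)
class ExpectedCounts:
    """Unrounded expected counts for one assay; a + b = n exactly."""

    assay: Assay
    n: int
    category_a: Fraction
    category_b: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "category_a", as_fraction(self.category_a))
        object.__setattr__(self, "category_b", as_fraction(self.category_b))
        if self.category_a < 0 or self.category_b < 0:
            raise ValueError("expected counts must be non-negative")
        if self.category_a + self.category_b != self.n:
            raise ValueError(
                f"expected counts {self.category_a} + {self.category_b} "
                f"do not total n = {self.n}"
            )

    @property
    def rounded(self) -> tuple[int, int]:
        """Half-up integers for display; category_b absorbs the residue so
        the pair still totals n."""
        a = round_half_up(self.category_a)
        return a, self.n - a

    @property
    def ratio(self) -> str:
        a, b = self.rounded
        return f"{a}:{b}"


def _require_positive_n(n: int) -> None:
    if n <= 0:
        raise ValueError(f"total count n must be positive, got {n}")


def expected_seed_set(model: GeneticModel, n: int) -> ExpectedCounts:
    """Expected infertile : developing counts among ``n`` ovules.

    The infertile fraction is exactly the female abort fraction.
    """
    _require_positive_n(n)
    _, abort = model.female_pool()
    infertile = n * abort
    return ExpectedCounts(Assay.SEED_SET, n, infertile, n - infertile)


def sensitive_fraction(model: GeneticModel) -> Fraction:
    """Probability that a progeny plant inherits zero mutant alleles."""
    viable, _ = model.female_pool()
    if viable is None:
        raise ValueError("all female gametes abort; no progeny possible")
    male = model.male_pool()
    return viable[0] * male[0]


def expected_progeny(model: GeneticModel, n: int) -> ExpectedCounts:
    """Expected resistant : sensitive counts among ``n`` genotyped progeny."""
    _require_positive_n(n)
    s = sensitive_fraction(model)
    return ExpectedCounts(Assay.PROGENY, n, n * (1 - s), n * s)


def expected_fg_phenotypes(model: GeneticModel, n: int) -> ExpectedCounts:
    """Expected proliferating : normal counts among ``n`` scored embryo sacs.

    Proliferation marks gametophytes with no functional wild-type allele,
    scored before abortion removes them, i.e. the pre-selection frequency of
    the fully mutant gamete class (class 2 from a tetraploid, class 1 from a
    diploid parent).
    """
    _require_positive_n(n)
    dist = model.gametes()
    proliferating = n * dist[dist.max_class]
    return ExpectedCounts(
        Assay.FG_PHENOTYPE, n, proliferating, n - proliferating
    )


def expected_counts(model: GeneticModel, assay: Assay | str, n: int) -> ExpectedCounts:
    """Dispatch to the appropriate assay expectation."""
    assay = Assay(assay)
    fn = {
        Assay.SEED_SET: expected_seed_set,
        Assay.PROGENY: expected_progeny,
        Assay.FG_PHENOTYPE: expected_fg_phenotypes,
    }[assay]
    return fn(model, n)


def offspring_dosage_distribution(model: GeneticModel) -> dict[int, Fraction]:
    """Mutant-dosage distribution of selfed offspring.

    Convolution of the viable female pool with the TE-weighted male pool.
    Under the recessive rule the quadruplex class has frequency 0, since
    fully mutant female gametophytes abort.
    """
    viable, _ = model.female_pool()
    if viable is None:
        raise ValueError("all female gametes abort; no offspring distribution")
    male = model.male_pool()
    out: dict[int, Fraction] = {
        d: Fraction(0) for d in range(model.parent.ploidy + 1)
    }
    for cf, ff in viable.items():
        for cm, fm in male.items():
            out[cf + cm] += ff * fm
    return out


def triploid_recovery_probability(
    te_male: FractionLike | float, triploid_fraction: FractionLike | float
) -> Fraction:
    """Joint chance of recovering a triploid through the mutant male route:
    the pollen transmission efficiency times the triploid rate among
    transmitted mutant progeny."""
    te = as_fraction(te_male)
    tri = as_fraction(triploid_fraction)
    for name, v in (("te_male", te), ("triploid_fraction", tri)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return te * tri
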