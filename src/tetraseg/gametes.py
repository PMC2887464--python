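"""Gamete-class frequencies for selfed polyploids under double reduction.

A tetraploid parent produces diploid gametes whose mutant-allele dosage
(0, 1 or 2 copies) follows tetrasomic segregation.  When quadrivalents form
and a crossover separates the locus from its centromere, both sister-chromatid
copies of one chromosome can end up in the same gamete — *double reduction* —
which converts heterozygous gamete classes into homozygous ones.  The
per-gamete probability of that event is the coefficient ``alpha``:

* ``alpha = 0``     — pure chromosomal segregation (no double reduction),
* ``alpha = 1/7``   — random chromatid segregation,
* ``alpha = 1/6``   — the maximum, reached for a locus unlinked to its
  centromere (the default used throughout this package).

With mutant dosage ``d`` in the tetraploid parent the gamete classes are

    f(2 mutant copies) = alpha * d/4       + (1 - alpha) * C(d, 2)/6
    f(1 mutant copy)   =                     (1 - alpha) * d*(4 - d)/6
    f(0 mutant copies) = alpha * (4 - d)/4 + (1 - alpha) * C(4 - d, 2)/6

i.e. with probability ``alpha`` the gamete doubles one random chromosome
(mutant with probability d/4) and with probability ``1 - alpha`` it receives
one of the C(4,2) = 6 unordered chromosome pairs.  All arithmetic is exact
(:class:`fractions.Fraction`); floats appear only when callers report.

Gametophytic selection is expressed as a :class:`SelectionModel`: a set of
gamete classes that abort on the female side (frequency weight 0) and a
relative transmission weight per class on the male side, the field's
transmission efficiency (TE).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping

__all__ = [
    "MAX_ALPHA",
    "RANDOM_CHROMATID_ALPHA",
    "DEFAULT_MALE_TE",
    "ParentGenotype",
    "GameteClassDistribution",
    "DominanceMode",
    "SelectionModel",
    "SegregationRegime",
    "gamete_frequencies",
    "enumerate_gametes",
    "apply_female_selection",
    "apply_male_selection",
]

#: Maximal double-reduction coefficient (locus unlinked to its centromere).
MAX_ALPHA = Fraction(1, 6)

#: Double-reduction coefficient under random chromatid segregation.
RANDOM_CHROMATID_ALPHA = Fraction(1, 7)

#: Default relative transmission weight of affected pollen classes.
DEFAULT_MALE_TE = Fraction(1, 10)

_TETRAPLOID_DOSAGE_NAMES = {
    0: "nulliplex",
    1: "simplex",
    2: "duplex",
    3: "triplex",
    4: "quadruplex",
}
_NAME_TO_DOSAGE = {v: k for k, v in _TETRAPLOID_DOSAGE_NAMES.items()}

FractionLike = Fraction | int | str


def as_fraction(value: FractionLike | float) -> Fraction:
    """Coerce ints, strings like ``"1/6"`` and floats to an exact Fraction.

    Floats are converted through their decimal repr (``0.1`` -> 1/10), not
    their binary expansion, so common decimal inputs stay exact.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


def validate_alpha(alpha: FractionLike | float) -> Fraction:
    """Validate a double-reduction coefficient, returning it as a Fraction.

    Raises ``ValueError`` outside the admissible range [0, 1/6].
    """
    a = as_fraction(alpha)
    if not (0 <= a <= MAX_ALPHA):
        raise ValueError(
            f"double-reduction coefficient must lie in [0, 1/6], got {a}"
        )
    return a


@dataclass(frozen=True)
class ParentGenotype:
    """A selfed parent: chromosome-set count and mutant-allele dosage.

    For tetraploids the dosage carries the classical names nulliplex (0),
    simplex (1), duplex (2), triplex (3) and quadruplex (4).
    """

    ploidy: int
    mutant_dosage: int

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(
                f"only diploid (2) and tetraploid (4) parents are supported, "
                f"got ploidy {self.ploidy}"
            )
        if not 0 <= self.mutant_dosage <= self.ploidy:
            raise ValueError(
                f"mutant dosage must lie in [0, {self.ploidy}], "
                f"got {self.mutant_dosage}"
            )

    @classmethod
    def from_name(cls, name: str) -> "ParentGenotype":
        """Build a tetraploid parent from a dosage name such as ``"duplex"``,
        or a diploid from ``"diploid_het"`` / ``"diploid_wt"``."""
        key = name.strip().lower()
        if key in _NAME_TO_DOSAGE:
            return cls(ploidy=4, mutant_dosage=_NAME_TO_DOSAGE[key])
        if key in ("diploid_het", "heterozygote"):
            return cls(ploidy=2, mutant_dosage=1)
        if key in ("diploid_wt", "wildtype"):
            return cls(ploidy=2, mutant_dosage=0)
        raise ValueError(f"unknown genotype name: {name!r}")

    @property
    def name(self) -> str:
        if self.ploidy == 4:
            return _TETRAPLOID_DOSAGE_NAMES[self.mutant_dosage]
        return {0: "diploid_wt", 1: "diploid_het", 2: "diploid_hom"}[
            self.mutant_dosage
        ]

    @property
    def gamete_ploidy(self) -> int:
        return self.ploidy // 2

    @property
    def gamete_classes(self) -> tuple[int, ...]:
        """Possible mutant dosages of a gamete (0..gamete ploidy)."""
        return tuple(range(self.gamete_ploidy + 1))


@dataclass(frozen=True)
class GameteClassDistribution:
    """Exact frequencies of gamete classes keyed by mutant dosage.

    Frequencies are Fractions, non-negative, and sum to exactly 1.
    """

    freqs: Mapping[int, Fraction]

    def __post_init__(self) -> None:
        freqs = {int(k): as_fraction(v) for k, v in self.freqs.items()}
        object.__setattr__(self, "freqs", freqs)
        if any(v < 0 for v in freqs.values()):
            raise ValueError(f"negative gamete frequency in {freqs}")
        total = sum(freqs.values())
        if total != 1:
            raise ValueError(f"gamete frequencies sum to {total}, not 1")

    def __getitem__(self, dosage: int) -> Fraction:
        return self.freqs.get(dosage, Fraction(0))

    @property
    def classes(self) -> tuple[int, ...]:
        return tuple(sorted(self.freqs))

    @property
    def max_class(self) -> int:
        return max(self.freqs)

    def items(self) -> Iterable[tuple[int, Fraction]]:
        return sorted(self.freqs.items())

    def relabelled_swapped(self) -> "GameteClassDistribution":
        """Swap mutant and wild-type labels (class c -> max_class - c)."""
        m = self.max_class
        return GameteClassDistribution({m - c: f for c, f in self.freqs.items()})

    def to_floats(self) -> dict[int, float]:
        return {c: float(f) for c, f in self.items()}

    def debug_str(self) -> str:
        """Serialize frequencies as exact "p/q" strings."""
        return " ".join(f"{c}:{f.numerator}/{f.denominator}" for c, f in self.items())


class DominanceMode(str, Enum):
    """Dominance behaviour of the mutant allele in the (diploid) gametophyte."""

    RECESSIVE = "recessive"
    DOMINANT = "dominant"


@dataclass(frozen=True)
class SelectionModel:
    """Sex-specific gametophytic selection rules.

    ``female_aborting`` lists gamete classes whose female gametophytes abort
    outright (they appear as infertile ovules).  ``male_weights`` gives each
    class a relative transmission weight through pollen in [0, 1]; weights
    are renormalised after application, so only ratios matter.

    Under the recessive rule only the fully mutant class aborts in the female
    and transmits at reduced efficiency through pollen; under the dominant
    rule every mutant-carrying class does.
    """

    mode: DominanceMode
    female_aborting: frozenset[int]
    male_weights: Mapping[int, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        weights = {int(k): as_fraction(v) for k, v in self.male_weights.items()}
        object.__setattr__(self, "male_weights", weights)
        object.__setattr__(self, "female_aborting", frozenset(self.female_aborting))
        for c, w in weights.items():
            if not 0 <= w <= 1:
                raise ValueError(f"male weight for class {c} out of [0, 1]: {w}")

    @classmethod
    def build(
        cls,
        mode: DominanceMode | str,
        gamete_classes: Iterable[int] = (0, 1, 2),
        male_te: FractionLike | float = DEFAULT_MALE_TE,
    ) -> "SelectionModel":
        """Standard rules for a given dominance mode.

        recessive: only the fully mutant gamete class aborts in the female
        and gets weight ``male_te`` in pollen (heterozygous gametes are fully
        functional); dominant: every mutant-carrying class aborts in the
        female and gets ``male_te`` in pollen.
        """
        mode = DominanceMode(mode)
        classes = tuple(sorted(gamete_classes))
        top = classes[-1]
        te = as_fraction(male_te)
        if mode is DominanceMode.RECESSIVE:
            aborting = frozenset({top})
            weights = {c: (te if c == top else Fraction(1)) for c in classes}
        else:
            aborting = frozenset(c for c in classes if c > 0)
            weights = {c: (te if c > 0 else Fraction(1)) for c in classes}
        return cls(mode=mode, female_aborting=aborting, male_weights=weights)

    def male_weight(self, dosage: int) -> Fraction:
        return self.male_weights.get(dosage, Fraction(1))


def gamete_frequencies(
    parent: ParentGenotype, alpha: FractionLike | float = 0
) -> GameteClassDistribution:
    """Exact gamete-class distribution of a parent under double reduction.

    Tetraploid parents yield diploid gametes in classes {0, 1, 2} per the
    closed form in the module docstring; diploid parents yield haploid
    gametes segregating d/2 mutant, and must use ``alpha = 0`` (double
    reduction has no meaning in ordinary disomic meiosis).
    """
    a = validate_alpha(alpha)
    d = parent.mutant_dosage
    if parent.ploidy == 2:
        if a != 0:
            raise ValueError("alpha must be 0 for a diploid parent")
        return GameteClassDistribution(
            {0: 1 - Fraction(d, 2), 1: Fraction(d, 2)}
        )
    w = 4 - d
    return GameteClassDistribution(
        {
            0: a * Fraction(w, 4) + (1 - a) * Fraction(comb(w, 2), 6),
            1: (1 - a) * Fraction(d * w, 6),
            2: a * Fraction(d, 4) + (1 - a) * Fraction(comb(d, 2), 6),
        }
    )


class SegregationRegime(str, Enum):
    """Enumeration regimes for the brute-force oracle."""

    CHROMOSOMAL = "chromosomal"
    RANDOM_CHROMATID = "random_chromatid"


def enumerate_gametes(
    parent: ParentGenotype, regime: SegregationRegime | str
) -> GameteClassDistribution:
    """Brute-force oracle: enumerate all equally likely diploid gametes.

    ``chromosomal`` draws one of the C(4,2) unordered chromosome pairs (no
    double reduction).  ``random_chromatid`` draws one of the C(8,2) = 28
    unordered chromatid pairs; the 4 sister pairs are the double-reduction
    outcomes, giving alpha = 4/28 = 1/7.  Independent of
    :func:`gamete_frequencies` by construction — pure counting.
    """
    if parent.ploidy != 4:
        raise ValueError("gamete enumeration is defined for tetraploid parents")
    regime = SegregationRegime(regime)
    d = parent.mutant_dosage
    chromosomes = [1] * d + [0] * (4 - d)
    if regime is SegregationRegime.CHROMOSOMAL:
        outcomes = [a + b for a, b in itertools.combinations(chromosomes, 2)]
    else:
        chromatids = [allele for allele in chromosomes for _ in range(2)]
        outcomes = [a + b for a, b in itertools.combinations(chromatids, 2)]
    n = len(outcomes)
    return GameteClassDistribution(
        {c: Fraction(outcomes.count(c), n) for c in (0, 1, 2)}
    )


def apply_female_selection(
    dist: GameteClassDistribution, model: SelectionModel
) -> tuple[GameteClassDistribution | None, Fraction]:
    """Abort the female-lethal classes and renormalise the survivors.

    Returns ``(viable, abort_fraction)``; ``viable`` is ``None`` in the
    degenerate case where every gamete class aborts.  The abort fraction is
    exactly the expected infertile-ovule proportion in a seed-set assay.
    """
    abort = sum(
        (f for c, f in dist.items() if c in model.female_aborting), Fraction(0)
    )
    if abort == 1:
        return None, abort
    viable = {
        c: f / (1 - abort)
        for c, f in dist.items()
        if c not in model.female_aborting
    }
    return GameteClassDistribution(viable), abort


def apply_male_selection(
    dist: GameteClassDistribution, model: SelectionModel
) -> GameteClassDistribution:
    """Weight each class by its pollen transmission efficiency, renormalised.

    Raises ``ValueError`` in the degenerate case where every weighted
    frequency is zero (no functional pollen).
    """
    weighted = {c: f * model.male_weight(c) for c, f in dist.items()}
    total = sum(weighted.values())
    if total == 0:
        raise ValueError("no transmissible male gametes under this model")
    return GameteClassDistribution({c: f / total for c, f in weighted.items()})
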