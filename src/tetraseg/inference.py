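"""Goodness-of-fit testing, model ranking and transmission-efficiency estimation.

Observed two-category counts (infertile:developing ovules, resistant:sensitive
seedlings, proliferating:normal embryo sacs) are compared with each candidate
genetic model by the Pearson chi-square statistic on two categories (df = 1),
computed on *unrounded* expected counts and without continuity correction.
A model is rejected when p < 0.05 (chi-square critical value 3.84 at df 1);
among the candidates, the best fit is the one minimising the larger of its
seed-set and progeny statistics, with ties broken by the sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple, Sequence

from scipy.stats import chi2

from .expectations import (
    Assay,
    ExpectedCounts,
    GeneticModel,
    expected_progeny,
    expected_seed_set,
)
from .gametes import FractionLike, as_fraction, validate_alpha

__all__ = [
    "DEFAULT_THRESHOLD",
    "CRITICAL_VALUE_DF1",
    "ObservedCounts",
    "ModelFit",
    "ModelComparison",
    "chisq_gof",
    "fit_all_models",
    "estimate_te",
    "TeEstimate",
    "estimate_te_from_triplex_ratio",
]

DEFAULT_THRESHOLD = 0.05
#: chi-square critical value at p = 0.05, df = 1.
CRITICAL_VALUE_DF1 = 3.841458820694124


@dataclass(frozen=True)
class ObservedCounts:
    """A printed or simulated two-category count pair for one assay."""

    assay: Assay
    category_a: int
    category_b: int
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        if self.category_a < 0 or self.category_b < 0:
            raise ValueError("observed counts must be non-negative")
        if self.total == 0:
            raise ValueError("observed counts must not both be zero")

    @property
    def total(self) -> int:
        return self.category_a + self.category_b

    @property
    def ratio(self) -> str:
        return f"{self.category_a}:{self.category_b}"


@dataclass(frozen=True)
class ModelFit:
    """Result of one chi-square test of observed counts against a model."""

    expected: ExpectedCounts
    chisq: float
    df: int
    p_value: float
    rejected: bool
    model: GeneticModel | None = None


def chisq_gof(
    obs: ObservedCounts,
    expected: ExpectedCounts,
    threshold: float = DEFAULT_THRESHOLD,
    model: GeneticModel | None = None,
) -> ModelFit:
    """Pearson chi-square test of a two-category observation (df = 1).

    Expected counts must be strictly positive in both categories and total
    the observed n; the statistic uses the unrounded expectations.
    """
    if obs.total != expected.n:
        raise ValueError(
            f"observed total {obs.total} does not match expected n {expected.n}"
        )
    if expected.category_a <= 0 or expected.category_b <= 0:
        raise ValueError(
            "expected counts must be strictly positive in both categories"
        )
    stat = float(
        (obs.category_a - expected.category_a) ** 2 / expected.category_a
        + (obs.category_b - expected.category_b) ** 2 / expected.category_b
    )
    p = float(chi2.sf(stat, df=1))
    return ModelFit(
        expected=expected,
        chisq=stat,
        df=1,
        p_value=p,
        rejected=p < threshold,
        model=model,
    )


@dataclass(frozen=True)
class ModelComparison:
    """One candidate scored on the seed-set and progeny assays together."""

    model: GeneticModel
    seed_fit: ModelFit
    progeny_fit: ModelFit

    @property
    def max_chisq(self) -> float:
        return max(self.seed_fit.chisq, self.progeny_fit.chisq)

    @property
    def total_chisq(self) -> float:
        return self.seed_fit.chisq + self.progeny_fit.chisq

    @property
    def accepted(self) -> bool:
        return not (self.seed_fit.rejected or self.progeny_fit.rejected)


def fit_all_models(
    obs_seed: ObservedCounts,
    obs_progeny: ObservedCounts,
    candidates: Sequence[GeneticModel],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ModelComparison]:
    """Score every candidate on both assays; return them best-first.

    Ranking is by the larger of the two chi-square statistics (a model fits
    only if both assays fit), ties broken by their sum.
    """
    if not candidates:
        raise ValueError("at least one candidate model is required")
    results = []
    for model in candidates:
        seed_fit = chisq_gof(
            obs_seed,
            expected_seed_set(model, obs_seed.total),
            threshold,
            model,
        )
        progeny_fit = chisq_gof(
            obs_progeny,
            expected_progeny(model, obs_progeny.total),
            threshold,
            model,
        )
        results.append(ModelComparison(model, seed_fit, progeny_fit))
    return sorted(results, key=lambda r: (r.max_chisq, r.total_chisq))


def estimate_te(mutant_count: int, wildtype_count: int) -> Fraction:
    """Transmission efficiency: mutant over wild-type progeny counts from a
    reciprocal cross of a heterozygote."""
    if wildtype_count <= 0:
        raise ValueError("wild-type progeny count must be positive")
    if mutant_count < 0:
        raise ValueError("mutant progeny count must be non-negative")
    return Fraction(mutant_count, wildtype_count)


class TeEstimate(NamedTuple):
    """A transmission-efficiency estimate; ``at_boundary`` flags clamping."""

    value: Fraction
    at_boundary: bool


def estimate_te_from_triplex_ratio(
    observed_triplex: int,
    observed_duplex: int,
    alpha: FractionLike | float,
) -> TeEstimate:
    """Invert the selfed-triplex offspring model for the pollen TE of fully
    mutant gametes.

    A selfed triplex parent under the recessive rule produces triplex
    offspring only through a heterozygous female gamete fertilised by a
    fully mutant (class 2) male gamete, so the triplex:duplex ratio among
    offspring identifies the class-2 male transmission weight ``w``:

        ratio(w) = F1 * w * g2 / (F0 * w * g2 + F1 * g1)

    with ``g`` the pre-selection gamete frequencies and ``F`` the viable
    female pool.  Solved exactly; values outside [0, 1] are clamped with
    ``at_boundary = True`` and a warning.
    """
    if observed_duplex <= 0:
        raise ValueError("duplex offspring count must be positive")
    if observed_triplex < 0:
        raise ValueError("triplex offspring count must be non-negative")
    a = validate_alpha(alpha)
    model = GeneticModel.standard("triplex", "recessive", alpha=a)
    g = model.gametes()
    viable, _ = model.female_pool()
    assert viable is not None
    r = Fraction(observed_triplex, observed_duplex)
    if observed_triplex == 0:
        return TeEstimate(Fraction(0), False)
    denom = g[2] * (viable[1] - r * viable[0])
    if denom <= 0:
        warnings.warn(
            "observed triplex:duplex ratio exceeds the model's range; "
            "TE clamped to 1",
            stacklevel=2,
        )
        return TeEstimate(Fraction(1), True)
    w = r * viable[1] * g[1] / denom
    if w > 1:
        warnings.warn("estimated TE exceeds 1; clamped", stacklevel=2)
        return TeEstimate(Fraction(1), True)
    return TeEstimate(w, False)
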