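"""Forward simulation of a selfed parent's ovule, progeny and FG phenotypes.

The simulator draws from exactly the distributions the expectation and
inference modules assume, so every pipeline stage can be exercised without
real data:

* each scored ovule receives a female gamete class from the parent's gamete
  distribution; aborting classes become infertile ovules,
* every viable ovule is fertilised (pollen is non-limiting) by a male gamete
  drawn from the TE-weighted pollen pool; a progeny plant is resistant iff
  its total mutant dosage is at least 1,
* embryo sacs are scored *before* selection (proliferating, doomed FGs are
  visible in cleared ovules), so FG classes come from the raw gamete
  distribution.

All sampling is multinomial through ``numpy.random.default_rng`` (PCG64);
a fixed seed gives identical counts across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np

from .expectations import (
    Assay,
    GeneticModel,
    standard_candidates,
)
from .gametes import FractionLike, SelectionModel, as_fraction
from .inference import ObservedCounts, fit_all_models

__all__ = ["SimulationConfig", "SimulationResult", "simulate_selfing", "simulate_selection_experiment"]


@dataclass(frozen=True)
class SimulationConfig:
    """What to simulate: the true model, assay sizes and the RNG seed.

    ``male_class2_weight`` optionally overrides the fully-mutant pollen
    transmission weight of the model's selection rule (``None`` keeps it).
    """

    model: GeneticModel
    n_ovules: int = 678
    n_genotyped: int = 352
    n_fg_scored: int = 162
    seed: int = 0
    male_class2_weight: FractionLike | float | None = None

    def __post_init__(self) -> None:
        for name in ("n_ovules", "n_genotyped", "n_fg_scored"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def effective_model(self) -> GeneticModel:
        if self.male_class2_weight is None:
            return self.model
        sel = self.model.selection
        top = max(sel.male_weights) if sel.male_weights else 2
        weights = dict(sel.male_weights)
        weights[top] = as_fraction(self.male_class2_weight)
        return replace(
            self.model,
            selection=SelectionModel(
                mode=sel.mode,
                female_aborting=sel.female_aborting,
                male_weights=weights,
            ),
        )


@dataclass(frozen=True)
class SimulationResult:
    """Simulated counts; an assay simulated at size 0 is ``None``."""

    seed_set: ObservedCounts | None
    progeny: ObservedCounts | None
    fg: ObservedCounts | None
    offspring_dosages: dict[int, int]

    def observed(self) -> list[ObservedCounts]:
        return [o for o in (self.seed_set, self.progeny, self.fg) if o is not None]


def _probs(fracs: list[Fraction]) -> np.ndarray:
    p = np.array([float(f) for f in fracs], dtype=float)
    return p / p.sum()


def simulate_selfing(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Draw one simulated dataset (seed set, progeny, FG counts).

    Progeny are drawn from the joint (viable female class, male class)
    multinomial; the realised offspring dosage table is returned alongside
    the two-category counts.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    model = config.effective_model()
    gametes = model.gametes()
    selection = model.selection

    # Seed set: female gamete classes; aborting classes -> infertile ovules.
    classes = list(gametes.classes)
    seed_set = None
    if config.n_ovules > 0:
        ovule_counts = rng.multinomial(
            config.n_ovules, _probs([gametes[c] for c in classes])
        )
        infertile = int(
            sum(
                k
                for c, k in zip(classes, ovule_counts)
                if c in selection.female_aborting
            )
        )
        seed_set = ObservedCounts(
            Assay.SEED_SET, infertile, config.n_ovules - infertile, model.label
        )

    # Progeny: joint female-viable x male-selected draw.
    viable, _ = model.female_pool()
    if viable is None and config.n_genotyped > 0:
        raise ValueError("all female gametes abort; cannot simulate progeny")
    dosages: dict[int, int] = {}
    progeny = None
    if config.n_genotyped > 0:
        assert viable is not None
        male = model.male_pool()
        pairs = [(cf, cm) for cf in viable.classes for cm in male.classes]
        joint = _probs([viable[cf] * male[cm] for cf, cm in pairs])
        pair_counts = rng.multinomial(config.n_genotyped, joint)
        for (cf, cm), k in zip(pairs, pair_counts):
            if k:
                d = cf + cm
                dosages[d] = dosages.get(d, 0) + int(k)
        sensitive = dosages.get(0, 0)
        progeny = ObservedCounts(
            Assay.PROGENY, config.n_genotyped - sensitive, sensitive, model.label
        )

    # FG phenotypes: pre-selection gamete classes; fully mutant -> proliferating.
    fg = None
    if config.n_fg_scored > 0:
        fg_counts = rng.multinomial(
            config.n_fg_scored, _probs([gametes[c] for c in classes])
        )
        proliferating = int(fg_counts[classes.index(gametes.max_class)])
        fg = ObservedCounts(
            Assay.FG_PHENOTYPE,
            proliferating,
            config.n_fg_scored - proliferating,
            model.label,
        )
    return SimulationResult(seed_set, progeny, fg, dosages)


def simulate_selection_experiment(
    truth: GeneticModel,
    n_replicates: int,
    seed: int,
    candidates: list[GeneticModel] | None = None,
    n_ovules: int = 678,
    n_genotyped: int = 352,
) -> float:
    """Parameter-recovery harness for the model-selection pipeline.

    For each replicate, simulate seed-set and progeny counts at the given
    assay sizes under ``truth``, rank all candidates (the six canonical
    hypotheses by default) with :func:`tetraseg.inference.fit_all_models`,
    and return the fraction of replicates in which the true model comes
    out on top.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if candidates is None:
        candidates = standard_candidates(alpha=truth.alpha)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        sim = simulate_selfing(
            SimulationConfig(
                model=truth,
                n_ovules=n_ovules,
                n_genotyped=n_genotyped,
                n_fg_scored=0,
            ),
            rng=rng,
        )
        ranked = fit_all_models(sim.seed_set, sim.progeny, candidates)
        if ranked[0].model.label == truth.label:
            hits += 1
    return hits / n_replicates
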