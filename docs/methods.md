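# Methods

## The genetic problem

A gametophytically lethal, T-DNA-tagged knock-out allele (*rbr-3*) of the
*Arabidopsis RETINOBLASTOMA RELATED* gene cannot be made homozygous in
diploids: homozygous-mutant female gametophytes abort, and mutant pollen
transmits poorly. Tetraploid genetics sidesteps this. A tetraploid parent of
unknown mutant dosage *d* ∈ {0..4} (nulliplex .. quadruplex) is selfed, and
three cheap assays are scored:

* **seed set** — infertile ovules vs developing seeds per silique,
* **progeny segregation** — resistant (R, at least one T-DNA copy) vs
  sensitive (S) seedlings on selection medium,
* **female-gametophyte (FG) phenotype** — embryo sacs with supernumerary
  nuclear divisions vs normal mature FGs, in cleared ovules.

Each candidate hypothesis (dosage × dominance mode) predicts a two-category
ratio for each assay; Pearson χ² against the observed counts selects the
dosage and settles whether the allele acts recessively or dominantly in the
(diploid) gametophyte.

## Gamete model

A tetraploid produces diploid gametes. Under pure chromosomal segregation a
parent with dosage *d* emits one of the C(4,2) = 6 unordered chromosome
pairs. With quadrivalent pairing and a crossover between locus and
centromere, both sister-chromatid copies of one chromosome can enter the
same gamete (**double reduction**), with per-gamete probability α. The
package uses the standard decomposition

    f(aa) = α·d/4       + (1−α)·C(d,2)/6
    f(Aa) =               (1−α)·d(4−d)/6
    f(AA) = α·(4−d)/4   + (1−α)·C(4−d,2)/6

— with probability α the gamete doubles one uniformly chosen chromosome
(mutant with probability d/4), otherwise it is an ordinary chromosome pair.
Benchmarks for α: 0 (chromosomal), 1/7 (random chromatid segregation) and
1/6, the maximum for a locus unlinked to its centromere. The *RBR* locus is
~45 cM from its centromere, so the default throughout is α = 1/6; an α = 0
mode is kept because one historical progeny expectation was computed without
double reduction.

The formula is never trusted on its own: `enumerate_gametes` is an
independent brute-force oracle that counts chromosome pairs (must equal the
closed form at α = 0) and all C(8,2) = 28 chromatid pairs, of which the 4
sister pairs are exactly the double-reduction outcomes (must equal the
closed form at α = 4/28 = 1/7). The test suite asserts both equalities
exactly for every dosage.

All probability arithmetic is `fractions.Fraction`. This is not pedantry:
the published χ² values are reproducible only from unrounded expected counts
(e.g. 678 × 2/9 = 150.667 infertile ovules, not the displayed 151; rounding
first gives χ² = 3.41 instead of 3.53). Floats appear only at the
reporting/statistics boundary.

## Selection rules

Sex-specific gametophytic selection, with TE the transmission efficiency
(mutant : wild-type progeny ratio from reciprocal crosses of a heterozygote):

* **female** — aborting gamete classes get weight 0 and appear as infertile
  ovules. Recessive rule: only the fully mutant class (aa) aborts
  (TE♀ = 0 for the allele); dominant rule: every mutant-carrying class
  aborts.
* **male** — pollen is non-limiting; selection only reweights the pollen
  pool. Affected classes transmit at relative weight 0.1, the TE estimated
  for mutant pollen in the diploid background. Recessive rule: weight 0.1 on
  the aa class only; dominant rule: 0.1 on every mutant-carrying class.
  These are the unique assignments that reproduce all five reproducible
  progeny expectations of the determination screen (324:28, 349:3, 27:325,
  91:261, 245:107 of 352).

Expected ratios follow directly: the infertile seed-set fraction is the
female abort fraction; a progeny plant is sensitive iff both gametes carried
zero mutant copies (product of the viable-female and TE-weighted-male
class-0 shares); proliferating FGs are the fully mutant gamete class
*before* abortion, since doomed embryo sacs are still visible in cleared
ovules. The offspring dosage distribution is the convolution of the two
selected pools — under the recessive rule the quadruplex class has
probability exactly 0, matching the empirical absence of quadruplex mutants.

## Inference

Two-category Pearson χ² with df = 1, no continuity correction (the published
statistics match the uncorrected form), expected counts unrounded, p-values
from the χ²₁ survival function (`scipy.stats.chi2.sf`). Zero *observed*
cells are legal (a confirmation group scored 208:0); zero *expected* cells
are an error. Significance defaults to p = 0.05 (critical value 3.84),
configurable. Candidates are ranked by the larger of their seed-set and
progeny statistics — a model fits only if both assays fit — with ties broken
by the sum.

`estimate_te_from_triplex_ratio` inverts the selfed-triplex offspring model:
triplex offspring arise only as (heterozygous female gamete) × (fully mutant
male gamete), so the triplex:duplex offspring ratio identifies the class-2
pollen weight w in closed form. Estimates outside [0, 1] are clamped and
flagged (`at_boundary`).

## Reference dataset and known discrepancies

The package bundles the observed counts of the original experiments
(`tetraseg/data/reference_counts.csv`): the six-model determination screen
(seed set 171:507 of 678; progeny 327:25 of 352) and two confirmation groups
(simplex: 16:250 and 321:86; triplex: 309:232 and 208:0). Three rows need
comment:

* **Simplex-recessive progeny (determination screen).** The historically
  reported expectation 295:57 (χ² 21.02) is not producible by *any*
  female-abortion × male-TE combination in this model family; the natural
  model gives ≈240:112 (χ² ≈ 99). The reference report computes and prints
  its own expectation and annotates the row as non-reproduced rather than
  imitating the published number. Since the screen's purpose is served by
  the row being strongly rejected either way, the model-selection conclusion
  is unaffected.
* **Triplex confirmation seed set.** The reported expected ratio 293:247
  totals 540 while the observed 309:232 totals 541; the reported χ² = 1.89
  is recovered exactly when the expectation is scaled to the observed total
  (293.04:247.96), which is what `fit_all_models` always does. Half-up
  display then reads 293:248.
* **Triplex confirmation progeny (208:0, reported χ² 1.71).** The statistic
  lies between the two defensible male-selection variants: χ² ≈ 1.55 with
  aa-pollen weight 0.1 and ≈ 1.73 with full aa-pollen abortion (weight 0).
  The weight is configurable (`male_te` on model constructors,
  `male_class2_weight` on the simulator config); the package asserts only
  non-rejection for this row and takes no position on which variant produced
  the published value.

## Synthetic data

`simulate_selfing` draws from exactly the distributions the expectations
assume: multinomial female gamete classes per ovule (aborting classes →
infertile), every viable ovule fertilised by a male gamete from the
TE-weighted pool (pollen non-limiting), resistance iff total dosage ≥ 1, FG
classes drawn pre-selection. Default assay sizes are the experimental ones —
678 ovules, 352 genotyped progeny, 162 scored FGs. Randomness is
`numpy.random.default_rng` (PCG64); a fixed seed reproduces counts exactly
across runs and platforms.

What the simulator deliberately does **not** emulate: post-fertilisation
seed abortion (endosperm/embryo lethality), aneuploid or unreduced-gamete
(triploid-bridge) offspring, ovule-number variation between siliques, or
genotyping/scoring error. Passing recovery tests therefore demonstrate the
statistical identifiability of the candidate models under the stated
sampling model, not robustness to those real-data complications.

`simulate_selection_experiment` is the parameter-recovery harness: simulate
counts at the experimental sample sizes, run the six-model selection, and
report the fraction of replicates recovering the truth. At 500 replicates
the duplex- and triplex-recessive truths are recovered in well over 95% of
replicates — unsurprising given the χ² separations of 10²–10³ between
candidates at these sample sizes. 500 replicates keeps the whole suite
around a few seconds while the binomial standard error on a ≥0.95 recovery
rate (≈1%) is already far smaller than the margin.

## Numerical and interface choices

* Display rounding is half-up, with category_b absorbing the residue so
  displayed pairs total n; machine-readable outputs carry full precision.
* Ratio separator is ASCII ":" on output; the Unicode ratio sign "∶" is
  accepted on input.
* Ploidy support is deliberately limited to diploid and tetraploid parents;
  anything else raises. Diploid parents require α = 0 (double reduction has
  no meaning in disomic meiosis).
* Degenerate pools (all female gametes aborting, e.g. a quadruplex-recessive
  or an α = 0 triplex-dominant parent; or zero total pollen weight) raise
  `ValueError` rather than returning renormalised nonsense.
* Reports carry no timestamps in the data section, so identical inputs give
  byte-identical output.

## Limitations

The model family is a two-sex, single-locus, infinite-pollen abstraction fit
to two-category counts; it cannot distinguish hypotheses that predict the
same two-category collapse (e.g. the exact pollen-side fate of aa gametes,
see above). Linked-locus double reduction as a function of centromere
distance and quadrivalent-pairing dynamics are out of scope: α is a free
coefficient in [0, 1/6], not derived from meiotic mechanics.
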