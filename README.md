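# tetraseg

Autotetraploid segregation analysis under double reduction: exact
gamete-class frequencies, gametophytic selection, and χ² model selection for
selfing experiments with a gametophytically lethal allele.

## The problem

Some mutations — for instance the T-DNA knock-out allele *rbr-3* of the
*Arabidopsis RETINOBLASTOMA RELATED* gene — kill the haploid gametophyte
generation outright, so they can never be made homozygous in a diploid and
their dominance behaviour cannot be read off ordinary segregation ratios.
Tetraploid genetics works around this: a tetraploid parent carrying *d*
mutant copies (*d* = 0..4: nulliplex, simplex, duplex, triplex, quadruplex)
produces *diploid* gametes, and the two-category ratios it leaves behind —
infertile : developing ovules, resistant : sensitive seedlings on selection
medium, proliferating : normal embryo sacs — discriminate both the unknown
dosage *d* and whether the allele acts recessively or dominantly in the
gametophyte.

`tetraseg` computes those expectations exactly and fits them to observed
counts. For a tetraploid parent with dosage *d* and double-reduction
coefficient α, the diploid gamete classes are

    f(aa) = α·d/4     + (1−α)·C(d,2)/6
    f(Aa) =             (1−α)·d(4−d)/6
    f(AA) = α·(4−d)/4 + (1−α)·C(4−d,2)/6

with α ∈ [0, 1/6] (0 = chromosomal segregation, 1/7 = random chromatid
segregation, 1/6 = the maximum, reached for a locus unlinked to its
centromere — the default). Sex-specific selection then removes aborting
classes on the female side and reweights pollen by per-class transmission
efficiencies (default 0.1 for affected classes); a Pearson χ² test (df = 1,
unrounded expected counts, no continuity correction) scores each candidate
dosage × dominance model, and the best fit is the model minimising the worse
of its seed-set and progeny statistics. All probability arithmetic is exact
rational (`fractions.Fraction`); floats appear only in the statistics and
reports. A seeded forward simulator (`tetraseg.synthetic`) generates selfing
datasets with the same statistical structure for testing and power analysis.

## Worked example

Rank the six candidate models against a selfing experiment that scored
171 infertile of 678 ovules and 327 resistant of 352 seedlings:

```sh
$ tetraseg fit --seed-obs "171:507" --progeny-obs "327:25"
# tetraseg fit
group              model    assay   n expected observed   chisq       p_value  rejected note
       Duplex, recessive seed_set 678  151:527  171:507    3.53  6.030000e-02     False
       Duplex, recessive  progeny 352   324:28   327:25    0.34  5.630000e-01     False
      Triplex, recessive seed_set 678  367:311  171:507  228.81  1.080000e-51      True
      Triplex, recessive  progeny 352    349:3   327:25  194.27  3.710000e-44      True
      Simplex, recessive seed_set 678   28:650  171:507  752.69 1.040000e-165      True
      ...
best model: Duplex, recessive (chi2 seed 3.53, progeny 0.34)
```

Only the duplex-recessive model survives at p = 0.05 (critical value 3.84,
df 1): the parent carried two recessive mutant alleles, homozygous-mutant
female gametophytes abort (expected infertile fraction 2/9 of ovules), and
mutant pollen transmits at a tenth of the wild-type rate — depleting mutant
classes in the pollen pool and raising the expected sensitive count from 22
to 28 of 352.

The same machinery answers point questions from Python:

```python
>>> from fractions import Fraction
>>> import tetraseg as ts
>>> triplex = ts.GeneticModel.standard("triplex", "recessive", alpha=Fraction(1, 6))
>>> ts.expected_fg_phenotypes(triplex, 100).ratio   # proliferating : normal
'54:46'
>>> ts.gamete_frequencies(ts.ParentGenotype(4, 3), Fraction(1, 6)).debug_str()
'0:1/24 1:5/12 2:13/24'
```

A triplex plant is expected to show proliferating (fully mutant) embryo
sacs in 13/24 ≈ 54% of ovules. And a simulated experiment round-trips
through the fitter:

```sh
$ tetraseg simulate --genotype duplex --seed 7
assay,category_a,category_b,group_label
seed_set,143,535,"Duplex, recessive"
progeny,336,16,"Duplex, recessive"
fg_phenotype,37,125,"Duplex, recessive"
```

`tetraseg report` prints the full reference analysis grid (the bundled
observed counts of the original determination screen and both confirmation
groups); one progeny row is annotated as non-reproduced — see
`docs/methods.md` for the details.

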