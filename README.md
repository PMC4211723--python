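# hetmig

Genotype–phenotype correlates for wild, weakly structured ungulate
populations typed at microsatellite panels.

Field studies of large mammals routinely collect three kinds of data on
the same animals: co-dominant marker genotypes, fitness-proxy phenotypes
(body mass, percent body fat), and GPS collar tracks that yield
migration timing. `hetmig` implements the statistical chain that
connects them:

- **Diversity and heterozygosity–fitness groundwork** — multilocus and
  single-locus heterozygosity (MLH/SLH), Hardy–Weinberg exact tests,
  Weir–Cockerham F_IS per winter-range group, and the g² identity
  disequilibrium statistic (David et al. 2007) with a permutation test.
  g² > 0 means inbreeding varies among individuals — the precondition
  for interpreting an MLH–fitness correlation as inbreeding depression.
- **Relatedness vs migration timing** — pairwise Queller–Goodnight
  relatedness, |day-difference| matrices for spring/fall migration
  initiation and termination, and Mantel / partial Mantel permutation
  tests with id-level bootstrap confidence limits (partials control for
  winter- or summer-range centroid distance). A negative Mantel r means
  related animals migrate closer together in time.
- **Bayesian phenotype models** — negative-binomial regression for
  migration-day counts with mtDNA-haplogroup, winter-range and age
  covariates; a hierarchical log-normal model for body mass and a
  hierarchical beta regression for body-fat fractions, both with
  per-individual random intercepts and the 17 SLH indicators.
  Inference is by posterior sign probabilities (an effect is flagged at
  ≥95% posterior mass on one side of zero), DIC model comparison, and a
  shrinkage-prior refit that guards against false-positive loci.
- **Migration phenology from GPS tracks** — minimum-convex-polygon
  demarcation of winter/summer ranges, migration initiation =
  permanent departure from the origin MCP, termination = settled
  arrival in the destination range, plus range centroids.
- **A ground-truth simulator** — seeded, study-shaped synthetic data
  (134 animals × 17 loci, matriline families, haplogroup-shifted fall
  timing, planted single-locus fat effects, GPS tracks) so every
  estimator in the chain can be validated against known truth.

## Worked example

```bash
python examples/01_genotype_statistics.py
```

```
134 individuals x 17 loci, 99.0% complete
mean MLH 0.777  (fraction of typed loci heterozygous)
HWE exact test at loc01: p = 0.275  (large p: no departure)
F_IS[NM] = -0.012  F_IS[NR] = +0.012  F_IS[RG] = -0.028  F_IS[SM] = -0.024
(values near 0: genotype proportions match random mating)
g2 = 0.0058 (p = 0.010); g2 > 0 means variance in inbreeding among
individuals, the precondition for MLH-fitness tests
```

The synthetic population is 99% genotyped, its four winter-range groups
sit at Hardy–Weinberg proportions (F_IS within ±0.03 of zero), and the
weak but nonzero g² (~0.01) says a small amount of inbreeding variance
is present — exactly the regime the simulator is calibrated to.

The one closed-form result worth knowing by heart: a negative-binomial
timing model with median intercept 2.932 and a haplogroup-2 coefficient
of −0.350 predicts

```python
>>> from hetmig import day_difference
>>> day_difference(2.932, -0.350)
(6, 5.542...)
```

i.e. haplogroup-2 animals end fall migration 6 days earlier (5.54 days
before rounding) than haplogroup-1 animals.

Other entry points: `examples/02_relatedness_and_mantel.py` (Mantel
battery), `examples/03_phenotype_models.py` (beta-fat fit, shrinkage
refit, day-shift prediction), `examples/04_migration_extraction.py`
(GPS → dates), `examples/05_full_pipeline.py` (everything, emitting the
three report tables). The same chain is scriptable from the shell:

```bash
hetmig simulate --seed 1 --out data/
hetmig genostats data/genotypes.csv --out stats/
hetmig relatedness data/genotypes.csv --out rel.csv
hetmig report --out run1 --seed 1
```

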