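# Methods

`hetmig` implements the analysis chain of a genotype–phenotype study on a
wild, weakly structured ungulate population: microsatellite diversity
statistics and heterozygosity–fitness screening, pairwise relatedness
versus migration-timing similarity, Bayesian phenotype regressions, and
migration phenology from GPS collars, plus a ground-truth simulator that
generates data shaped like the study so the whole chain can be exercised
and calibrated without field data.

## Genotype statistics

Genotypes are two unordered allele labels per individual and locus;
labels are opaque strings (fragment sizes and letter codes behave
identically) and the missing codes `0`, `000`, empty, and `NA` are
normalised to a single internal marker.

- **MLH / SLH.** Single-locus heterozygosity is the 0/1 indicator per
  typed locus; multilocus heterozygosity is the mean of an individual's
  non-missing indicators (per-individual renormalisation over typed
  loci). The identity MLH = mean(SLH) is fuzz-tested.
- **Hardy–Weinberg exact test.** The Levene conditional distribution of
  genotype arrays given allele counts. Arrays are enumerated exhaustively
  when a cheap upper bound says there are at most 10⁵ of them (in
  practice: biallelic and small multiallelic cases); otherwise 10⁴
  Monte-Carlo shuffles of the gene copies. The p-value sums probabilities
  of arrays no more probable than the observed one. Monomorphic loci
  return p = 1 with a warning.
- **F_IS.** Weir & Cockerham (1984) within-population f. Variance
  components b (among individuals) and c (within individuals) are summed
  over alleles and loci before the final ratio f = 1 − Σc/Σ(b+c)
  (ratio-of-sums). All individuals heterozygous at a biallelic locus
  gives f = −1 exactly.
- **g² identity disequilibrium.** The David et al. (2007)
  missing-data-tolerant multilocus estimator: for each locus pair, the
  mean same-individual cross-product of heterozygosity indicators
  (normalised by individuals typed at both loci) and the mean
  cross-individual product (normalised by cross pairs); both pooled over
  all locus pairs before the final ratio minus one. The permutation null
  shuffles each locus's SLH column independently across individuals
  (destroying among-locus covariance while keeping per-locus
  heterozygosity and missingness), p = (1 + #{g²_perm ≥ g²_obs})/(B+1),
  B = 1000 by default. RMES-style software is not used anywhere, so
  agreement is established behaviourally: g² ≈ 0 under random union of
  gametes, g² > 0 under a mixture containing inbred lineages, and
  uniform p-values under the null (type-I error in [0.02, 0.09] over 200
  simulations).

## Queller–Goodnight relatedness

Per dyad and locus, numerator 0.5·(δ_ac+δ_ad+δ_bc+δ_bd) − p_a − p_b and
denominator 1 + δ_ab − p_a − p_b, with reference frequencies from the
full sample (the focal dyad is not excluded). Numerators and
denominators are summed across loci before dividing (ratio-of-sums, the
multilocus convention of the standard relatedness programs), and the two
directed estimates are averaged. Dyads sharing no typed locus are NaN;
dyads sharing fewer than five are flagged but kept. Calibration:
simulated parent–offspring, half-sib and unrelated dyads at 17 loci give
means 0.5 / 0.25 / 0 within ±0.03 at 200 dyads.

## Mantel machinery

Mantel r is the Pearson correlation over the n(n−1)/2 upper-triangle
pairs; masked dyads are excluded pairwise. The permutation null jointly
permutes rows and columns of one matrix; the p-value is two-sided on
|r|, (1 + #{|r_perm| ≥ |r_obs|})/(B+1), B = 10 000 by default. The
partial statistic residualises both matrices on the conditioning matrix
element-wise (Smouse–Long–Sokal) and permutes the residualised first
matrix.

Confidence limits are a package convention: ids are resampled with
replacement, r recomputed on the induced submatrix with pairs formed by
two copies of the same id excluded, and 95% percentile bounds taken over
1000 draws. Coverage of a planted correlation is ~95% (checked ≥85% at
40 replicates, n = 60, in the suite to keep runtime bounded).

## Bayesian phenotype models

Three likelihoods share one inference convention:

- **Negative-binomial timing model** — y_i ~ NB(μ_i, r),
  log μ_i = x_iᵀβ, for day counts relative to the earliest migrant;
  covariates are standardized age, winter-range dummies (NM reference)
  and mtDNA-haplogroup dummies (haplogroup 1 reference).
- **Log-normal mass model** — log mass_ij = x_ijᵀβ + b_i + ε_ij with a
  per-individual random intercept; linear or quadratic standardized age.
- **Beta body-fat model** — fat_ij ~ Beta(μ_ij φ, (1−μ_ij) φ),
  logit μ_ij = x_ijᵀβ + b_i; the covariate set holds the 17 SLH
  indicators plus age, a March-capture indicator and winter-range
  dummies. Percent input is divided by 100; exact 0/1 values are pulled
  inside the interval with (y(n−1)+0.5)/n.

Standardization is (x − mean)/(2·SD) with the population (n)
denominator, putting continuous and binary predictors on a comparable
scale. Priors (configurable): β ~ N(0, 10²), NB dispersion r and beta
precision φ ~ Gamma(0.1, 0.1), σ_b and σ_ε ~ half-Cauchy(5). These are
declared package defaults for a weakly informative setup, not a
reconstruction of any particular prior choice.

Samplers are treated as a contract (R-hat < 1.05, adequate ESS), not a
mechanism; the implementations are:

- NB: adaptive-covariance random-walk Metropolis on (β, log r), several
  proposals per recorded iteration (the likelihood is cheap and walk
  mixing is the binding constraint), sampled in a mean-centered column
  parameterization and mapped back exactly.
- Log-normal: conjugate Gibbs for β and b, univariate slice sampling on
  log σ_b and log σ_ε.
- Beta: Metropolis-within-Gibbs — an adaptive block for β (centered
  parameterization, several proposals per sweep), vectorised
  per-individual random-intercept steps, slice updates for log φ and
  log σ_b, plus two moves that break the model's slow directions: a
  likelihood-invariant intercept/random-intercept-mean transfer, and an
  interleaved non-centered rescaling of (σ_b, b) that de-funnels the
  many singleton individuals.

Defaults are 4 chains × 10 000 iterations with 25% burn-in; the test
suite and acceptance script run shorter chains (typically 2 × 2000–10 000)
to stay within their runtime envelope — convergence diagnostics are
computed and reported either way. Adaptation is frozen at the end of
burn-in so the retained chains satisfy detailed balance.

Summaries per coefficient: posterior median and the probability mass on
each side of zero; an effect is "flagged" when ≥95% of the posterior
lies on one side. DIC = mean deviance + pD with pD = var(deviance)/2
(single-run computable); the Spiegelhalter plug-in pD (mean deviance
minus deviance at the posterior-mean parameters) is reported alongside.
The variance form is unstable when a scale parameter sits on its
boundary (σ_b ≈ 0); the plug-in form is then the more interpretable of
the two. Deviance is conditional on the random intercepts. Residuals
are observed minus posterior-median prediction, carried with the
categorical design labels so group-wise residual patterns can be
inspected.

The shrinkage refit replaces the non-intercept coefficient priors with
N(0, sd²) where sd defaults to the SD of the original fit's median
coefficients (~0.14 on study-shaped data), and reports which flags
survive — a guard against false-positive single-locus effects.

The day-shift translation for the timing model is
exp(β₀) − exp(β₀ + β_level) at reference covariate values, rounded half
away from zero; the published medians (2.932, −0.350) give 5.54 → 6
days.

## Migration phenology

Dates are Julian day-of-year integers. The earliest-migrant correction
subtracts the minimum date, turning dates into day counts. Timing
distance is |d_i − d_j| in days; centroid distance is Euclidean meters
in a projected plane (geographic coordinates are not reprojected —
planar input is required).

Extraction from a GPS track, per season (spring window Mar 1–Jul 15,
fall Sep 1–Dec 15, both configurable): the origin range is the convex
hull (MCP) of fixes before the window; initiation is the last in-window
fix inside that hull with no later re-entry ("directed movement without
return" — a brief excursion that comes back does not count). The
destination hull is built from post-window fixes and dilated by the
95th-percentile residency radius, because a short post-window sample
undersamples the range the animal actually uses; termination is the
first fix inside the dilated destination region, provided the animal
never returns to the origin hull afterwards. Boundary fixes count as
inside. Animals that never leave the origin range are flagged and
excluded from that season's analyses. The operational rule is a stated
convention validated against synthetic ground truth (recovery within
one fix interval for ≥95% of tracks); the original demarcations it
stands in for were partly manual.

## Synthetic-data generator

The generator is the package's definition of the study conditions; all
of its defaults are fixed:

- 134 individuals × 17 loci, 8 alleles per locus from Dirichlet(1)
  frequencies, 1% missing calls; winter-range groups NM/NR/RG/SM sized
  30/30/44/30.
- Matriline families of 4–6 individuals from hidden parents (half of
  the families share a sire); mtDNA haplogroups (2 by default, 60/40)
  inherited matrilineally. A fraction 0.04 of individuals are
  selfed-lineage offspring (f = 0.5), giving var(f) ~ 0.01 — and hence
  an expected g² near the weak 0.01-level identity disequilibrium of
  the emulated population — while keeping mean f ~ 0.02 so per-locus
  genotype proportions stay close to Hardy–Weinberg expectation, as in
  the emulated population.
- Migration: fall termination counts are NB(r = 5) with log-mean
  2.932 − 0.350·[haplogroup 2] + winter-range effects (0.1768, −0.270,
  −0.440) − 0.095·std age + a matriline-shared effect u_f ~ N(0, 0.5²).
  The family effect is what creates the relatedness–timing covariance;
  0.5 on the log scale makes the fall Mantel r negative in every tested
  seed (mean ≈ −0.03, versus −0.04/−0.05 in the emulated study).
  Initiation precedes termination by 1 + Poisson(3) days; spring is
  analogous without haplogroup or range effects. Per-season missingness
  reproduces the study sample sizes (104 spring, 95 fall, mtDNA subset
  81).
- Condition: one or two capture records per individual (102 December,
  79 March, 47 both; 181 records). Fat is Beta(φ = 150) with logit mean
  −2.15 − 0.24·SLH(loc02) + 0.18·SLH(loc12) − 0.05·std age − 0.52·March
  + range effects + N(0, 0.15²) individual effect; φ = 150 and the
  individual SD were chosen so the posterior SD of a single-locus
  coefficient is ≈0.1 at study scale, the information content the
  emulated analysis displays. Mass is log-normal with a quadratic age
  effect (0.10, −0.08), March effect −0.10, σ_b = 0.06, σ_ε = 0.04
  around a 72-kg intercept. Ages are uniform integers 1–11.
- Tracks: damped-random-walk residency (sd 200 m) at winter and summer
  centers 30 km apart, a linear transit between the true dates, fix
  interval 30 min / 60 min / 5 h per animal, and 50 m measurement
  jitter.

What the generator does **not** emulate: genotyping error and null
alleles, linkage between loci, spatial habitat structure beyond group
centroids, weather/phenology drivers of timing, collar fix failures,
and real pedigree depth beyond two generations. Passing tests therefore
demonstrate that the estimators and models recover the structures they
target at the study's scale and noise level — not that the biological
conclusions of any particular field dataset are correct.

## Numerical and design choices

- All randomness flows through seeded `numpy` generators; per-chain and
  per-stream seeds derive from `SeedSequence` spawns, and every
  randomized operation is bit-reproducible under a fixed seed.
- Permutation p-values use the add-one convention ((1 + hits)/(B + 1)),
  so p = 0 is impossible.
- The Mantel permutation loop is vectorised and chunked to cap memory;
  matrix symmetry is enforced exactly (upper triangle mirrored) before
  output.
- Relatedness reference frequencies include the focal dyad; the
  alternative (exclusion) changes estimates by O(1/n) and is not
  implemented.
- Coancestry-style matrices from other programs can be supplied to the
  Mantel layer through the shared matrix CSV format (ids in the first
  row/column, `NA` diagonal).
- Pipeline outputs carry a provenance header (package version, seed,
  config hash); the hash covers analysis settings only, not output
  paths, so identical analyses are byte-identical.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the chain at the study's
natural scale (134 × 17 genotypes, 181 condition records, 95–104
migration records) but with shortened MCMC (2 chains × 2000–5000
iterations), reduced permutation counts (typically 199–999), and
replicate counts of 10–200 depending on the quantity; these sizes are
the package's choices for routine verification, and all of them can be
raised through the public interfaces.

## Known limitations

- Exact numerical agreement with the historical tools behind the
  emulated analysis (relatedness software settings, the confidence-limit
  procedure of the original Mantel library, RMES's g² output, JAGS's
  samplers) is not claimed anywhere; conventions are documented above
  and tested against theory, brute force, or independent libraries
  instead.
- The beta and log-normal models assume the random intercept is the
  only repeat-capture structure; serial correlation beyond it is not
  modelled.
- The MCP demarcation assumes residency–transit–residency tracks; slow
  drifting migrations without a clear departure produce flagged,
  missing dates rather than estimates.
- DIC's variance-form pD overestimates for hierarchical models whose
  scale posteriors touch zero; both pD variants are reported so this is
  visible.
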