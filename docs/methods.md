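# Methods

`gmatrixlab` simulates pedigreed artificial-selection experiments on two
quantitative traits and estimates and compares the additive genetic
variance–covariance matrix **G**. The traits are modeled on the analysis
scale used throughout: trait 0 is flower number, natural-log transformed
and multiplied by 50 (so its scale is comparable to the second trait);
trait 1 is specific leaf area (SLA, cm²/g). A positive genetic covariance
between these traits is the target of the simulated selection regime:
disruptive correlational selection that tries to erode the covariance
while leaving the trait means alone.

## Generative model

Breeding values follow the additive infinitesimal model over an explicit
pedigree. Founders draw a ~ MVN(0, G); an offspring of sire s and dam d
receives ½(a_s + a_d) plus an independent Mendelian-sampling deviation
with covariance ½·G·(1 − (F_s + F_d)/2), where F is a parent's inbreeding
coefficient. This makes cov(a_i, a_j) = A_ij · G exactly, with A the
additive (numerator) relationship matrix — the covariance structure the
animal model assumes. Phenotypes add an independent MVN(0, E)
environmental deviation to the trait means. The integer flower count is a
derived display column, `round(exp(flower_scaled/50))`; simulation and
estimation operate on the analysis scale.

The model is deliberately minimal: no dominance, epistasis, maternal
effects, genotype-by-environment interaction, mutation, or major-effect
loci, and no mortality or germination failure. Consequences: parameter
recovery and calibration results here certify the estimation machinery
under its own assumptions; they do not show how the pipeline behaves under
model misspecification (e.g., a covariance maintained by one segregating
major-effect locus, which an infinitesimal simulator cannot produce).

## Breeding design and the selection experiment

The base population uses a circulant crossing design: one male and one
female founder per capsule, the female of family *i* mated to the males of
families *i+1, i+2, i+3* (mod n). This yields full-sib, maternal half-sib
and paternal half-sib links between neighbouring families — the
relationship structure that makes G estimable. The emitted crosses are
thinned uniformly at random to the requested number of base families
(default 120 from 103 founder pairs); the exact thinning rule used to
arrive at the historical base population is not recoverable, so no claim
is made that the simulated base pedigree reproduces it individual by
individual.

Each of the (default four) selection rounds, per line:

1. **Measure** males only (`measured = sex == male`); females are bred but
   never phenotyped for analysis, mirroring the study protocol.
2. **Family means** over measured males; families with no measured male
   drop out.
3. **PCA** of the z-standardized family means (standardization is a design
   choice — the two traits' raw scales differ and the differentials are
   then in interpretable PC-score SD units). Sign convention: PC1's SLA
   loading ≥ 0 and det(loadings) = +1, so angles and score signs are
   stable across runs.
4. **Select** 8 families: the 4 most positive plus 4 most negative PC2
   scores for selection lines (deterministic, ties by family id); a
   uniform draw for the control line.
5. **Choose parents**: a uniformly random female, and the measured male
   nearest the family mean in cohort-standardized trait space
   (deterministic given the standardization; ties by id). A selected
   family without a usable pair is replaced by the next-ranked family with
   a warning.
6. **Breed** the next 24 families with the same circulant design. The
   final round grows more offspring per family (default 18, ≈9 measured
   males) to give the G-estimation sample.

Defaults mirror the study scale: 120 base families at 5 offspring each
(≈300 measured base males), 24 families × 5 offspring in rounds 1–3 (≈60
males per line per generation), and ≈216 measured males per line in the
final generation. Reported selection differentials per generation are
mean(|PC2|) of selected minus mean(|PC2|) of all (disruptive) and the
plain mean differences on PC1/PC2 (directional, to monitor inadvertent
selection on the means).

One known artefact of determinism: because both selection lines apply the
same deterministic PC2 rule to the same base generation, they choose the
same 8 base families and share most founding parents; replicate lines
diverge through dam choice and Mendelian sampling only. The real
experiment appears to have spread selected families between its two
replicate lines.

All randomness flows from one master seed through independent substreams
labeled by (line, round, stage), so the experiment is bit-reproducible and
single stages can be replayed.

## REML estimation of G

The bivariate animal model is y = Xb + Za + e with per-trait intercepts,
a ~ N(0, G ⊗ A), e ~ N(0, E ⊗ I). Marginalizing unmeasured pedigree
members leaves var(y) = G ⊗ A_mm + E ⊗ I with A_mm the relationship
matrix among measured individuals, so the restricted likelihood needs only
A_mm; ancestors re-enter through cov(a, y) = G ⊗ A_{all,m} when predicting
breeding values.

Numerics:

- A is built by the tabular method (A_ii = 1 + F_i, A_ij averaged over the
  later individual's parents) in topological order.
- With A_mm = U D U′, rotating the data by U′ block-diagonalizes var(y)
  into 2×2 blocks d_i·G + E; one restricted-log-likelihood evaluation is
  then O(n) after a single symmetric eigendecomposition.
- G and E are optimized through log-Cholesky factors, so both stay PSD by
  construction; the covariance-constrained fit (for the likelihood-ratio
  test of cov_A = 0) pins G's off-diagonal Cholesky entry at zero.
- Default optimizer: Nelder-Mead from three starts (balanced, G-dominant,
  E-dominant splits of the sample phenotypic covariance) followed by an
  L-BFGS-B polish; relative log-likelihood tolerance 1e−8. Resampling
  loops use a verified fast path — a single quasi-Newton run from the
  balanced start (it matched the multi-start optimum exactly in benchmark
  fits of this problem class, and likelihood-ratio statistics agreed to
  3·10⁻⁵) with a Nelder-Mead fallback.
- Standard errors come from the inverse of a central-difference Hessian of
  the negative restricted log-likelihood taken directly in
  variance-component space at the optimum (the convention ASReml-style
  software reports); heritability SEs by the delta method. On simulated
  data at n = 2000 these SEs track the empirical sampling SD to within a
  few percent (slightly conservative). They remain Wald SEs: symmetric
  intervals on right-skewed variance estimates undercover slightly on the
  low side, and simultaneous coverage of several elements is necessarily
  below per-element coverage.
- BLUPs solve the mixed-model equations at the REML estimates for every
  pedigree member, including unmeasured ancestors.

The LRT of cov_A = 0 uses the χ²(1) upper tail of 2·Δ(restricted
log-likelihood), floored at zero. The covariance is an interior parameter
(not a boundary), so the χ²(1) reference applies; simulated calibration at
the null sits near 4% rejection at α = 0.05.

## G-matrix comparison

**Eigenstructure ellipse.** Axis lengths √(λ_i·q) with q the χ²(2)
quantile at 95% coverage (≈5.991); the angle is the leading eigenvector's
direction, flower-number axis toward SLA axis, mapped into [0, 180)°. With
this trait order a positive genetic covariance gives an angle below 90°
and a negative one above 90°. Isotropic matrices return angle 0 by
convention.

**Randomization test.** Null hypothesis: two populations share one G.
Each iteration pools a fixed-size subsample of measured individuals from
both populations, refits the animal model on the pooled data under the
joint pedigree, and records the three ellipse parameters; p-values are
two-sided (doubled smaller tail) with an add-one correction. Non-converged
iterations are dropped; >20% dropped flags the result unreliable. A
caveat established during development and worth knowing when reading such
p-values: the test is calibrated only when the pooled-subsample fits have
roughly the same precision as the fit that produced the observed value.
When the observed G comes from a much larger sample than the pooled
draws, the test is conservative (it loses power but never manufactures
significance) — which is the regime the published analysis operated in.

**Random skewers.** Unit-length selection gradients β (uniform on [−1,1]²,
normalized) are applied to both matrices; the statistic is the mean
absolute vector correlation (cosine) between the responses G₁β and G₂β.
The absolute convention measures alignment of response directions
irrespective of orientation sign and is the convention under which
published comparisons of this kind are reported; the signed mean is
returned alongside. `p_similarity` is the fraction of independent random
unit-vector pairs whose |cosine| exceeds the observed mean — small values
mean the matrices agree beyond chance. Default 1000 skewers
(Monte-Carlo SE of the mean is reported); the desk-reproduction targets
use ≥10⁴.

**Founder BLUP resampling.** To ask what genetic correlation a line
founded by a handful of individuals could start from, k = 12 individuals
(an effective founding size allowing for matings among relatives within
16 actual founders) are drawn without replacement from the base
generation's BLUPs, and the Pearson correlation of the two BLUP components
is recorded; 1000 draws give the distribution. BLUP correlations
overstate the genetic correlation (shrinkage makes them anticonservative
for this use), which biases this check against finding small correlations
— the direction that makes its conclusion safe.

## Problem sizes used in the test suite

The statistical guarantees are exercised at sizes chosen to make the
asymptotics they rely on valid while keeping simulations practical:
parameter recovery at n = 2000 (200 independent full-sib families of 10,
50 replicates); LRT calibration at 240 measured (40 × 6, 500 replicates);
randomization-test type-I error with populations of 128 measured (16 × 8),
subsample 64 per population (so pooled fits match the observed fit's
precision), 99 iterations, 200 runs; power against an eroded covariance
with populations of 420 measured (30 × 14), subsample 210 per population
(again precision-matched), genetic correlations +0.64 vs −0.90 and trait
variances in the study's 1:7 ratio — the anisotropy is
essential, since with equal trait variances the pooled null G is nearly
isotropic and its ellipse angle carries no information.

## Limitations

- Only the bivariate trait case is supported and tested.
- Wald standard errors, not profile or sampling-based intervals.
- The randomization test's calibration depends on subsample sizing as
  described; it is reported, not corrected.
- The simulator's replicate selection lines share base-generation founders
  (see above).
- Selection differentials are in PC-score SD units of each (line,
  generation) PCA and are not comparable across generations on an absolute
  scale.
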