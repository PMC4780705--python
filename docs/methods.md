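# Methods

## The statistical problem

A single genetic variant is tested for association with K quantitative
traits measured on n unrelated individuals. Testing each trait separately
wastes power when the variant is pleiotropic, while classical multivariate
tests (MANOVA and relatives) lose power when most of the K traits carry no
signal. The package implements a maximum heritability test (MHT) and a
trait-deleting variant (MHT-O) designed to stay powerful in the presence
of many noise traits, alongside three standard benchmarks.

## Model and statistics

Each trait follows the marginal working model

    Y_k = alpha_k + beta_k X + eps_k,        k = 1..K,

with X the genotype score (minor-allele count 0/1/2 or a dosage in
[0, 2]). The total phenotypic covariance decomposes as V_P = V_G + V_R,
where V_G = var(X)·beta betaᵀ is the rank-one covariance explained by the
variant and V_R the covariance of the OLS residuals. All variances use
the 1/n denominator with no Bessel correction; every statistic below is a
ratio in which the convention cancels.

For a weight vector w, the combined trait wᵀY has heritability
h_w² = wᵀV_G w / wᵀV_P w. Maximising over w gives

    T_MHT = lambda_max(V_G V_P⁻¹) = var(X) · betaᵀ V_P⁻¹ beta ∈ [0, 1),

the largest heritability achievable by any linear combination of the
traits. T_MHT relates to the Hotelling-type quadratic form
t = var(X)·betaᵀV_R⁻¹beta through T = t/(1 + t) (Sherman–Morrison), and to
one-predictor Wilks' Λ through Λ = 1/(1 + t) = 1 − T. MHT, Hotelling and
MANOVA are therefore strictly monotone transforms of one another, and
their permutation p-values coincide; only their finite-sample reference
distributions differ.

MHT-O addresses noise traits by backward deletion: starting from all K
traits, it repeatedly removes the trait whose deletion leaves the largest
T_MHT among the survivors, recording T_MHT,r at every panel size
r = K..1 (ties in the argmax break toward the smallest trait index, a
determinism choice). Each T_MHT,r is converted to a p-value p_r by
permutation, and the MHT-O statistic is min_r p_r.

## Single-layer permutation calibration

Naively, min_r p_r needs a second permutation layer for calibration. The
package uses the single-layer scheme in which one set of B genotype
shuffles serves both purposes. With b = 0 the observed data and b = 1..B
the shuffles,

    p_r^(b) = #{d in 0..B : T_MHT,r^(d) > T_MHT,r^(b)} / B
    p^(b)   = min_r p_r^(b)
    p-value(MHT-O) = #{b >= 1 : p^(b) < p^(0)} / B.

The plain MHT p-value is #{b >= 1 : T_MHT,K^(b) >= T_MHT,K^(0)} / B.
Inequalities are implemented exactly as written: the per-size transform
uses strict ">" over all B+1 rows with denominator B (so p_r^(b) can reach
1 but not 1 + 1/B, a slight non-uniformity), and the final comparison uses
strict "<". Ties between continuous statistics occur with probability
zero; the fully degenerate all-tied column yields every p_r^(b) = 0 and is
documented rather than adjusted. Both final p-values have resolution 1/B,
which the results record. The permutation count matters at small alpha:
at B = 200 the discreteness of min-p inflates rejection rates at
alpha = 0.01 noticeably, which is why the experiment defaults keep
B = 1000.

### Computational strategy

Two algebraic facts make the permutation test cheap:

1. Because OLS residuals are orthogonal to the centred genotype, V_P
   equals the plain 1/n sample covariance of the traits — invariant under
   genotype shuffling. Only beta must be re-estimated per shuffle, and all
   B+1 slope vectors come from a single (K×n)(n×(B+1)) matrix product.
2. The marginal fit of one trait does not involve the other traits, so
   T_MHT on a subset equals the quadratic form over the corresponding
   subvector/submatrix of the full-panel beta and V_P. One estimation pass
   per permutation serves all ~K²/2 subset evaluations of the greedy path.

Deletion scores along the path come from rank-one downdates of the running
V_P inverse (removing row/col i of a matrix with known inverse M gives
inverse M' = M − m_i m_iᵀ/M_ii restricted to the survivors), evaluated for
all candidate deletions at once and batched across all B+1 permutations.
Unit tests pin this machinery to naive per-permutation re-estimation and
to brute-force subset search. Matrix solves on user-facing paths go
through Cholesky factorisations with explicit failure signalling; a V_P
with reciprocal condition number below 1e-12 raises an error naming trait
redundancy as the likely cause, rather than falling back to a
pseudo-inverse — a singular V_P means duplicated traits, which a deletion
path cannot rank meaningfully.

Randomness: each permutation ensemble draws its B shuffles from one
seeded NumPy generator; simulation replicates use per-replicate substreams
keyed (seed, replicate) so experiments are reproducible and resumable.
The package itself runs single-threaded, so results do not depend on any
worker scheduling.

## Benchmark tests

* SUM_SCORE sums the signed standardised score statistics
  Z_k = sqrt(n)·corr(x, y_k) and refers S/sqrt(1ᵀR1) to N(0,1), with R
  the trait correlation matrix. The signed form was chosen (over summing
  squares) because it reproduces the benchmark's characteristic behaviour:
  strong when effects share a direction, nearly blind when they cancel or
  concentrate in one trait. The squared variant remains available behind
  a flag for sensitivity analysis.
* TATES sorts the univariate p-values and takes
  min_j m_e·p_(j)/m_e(j), with m_e(j) the effective number of independent
  tests among the j most significant traits, computed from the eigenvalues
  lambda_i of their correlation matrix as
  sum_i [1(lambda_i >= 1) + (lambda_i − floor(lambda_i))]. The original
  method maps trait correlations to p-value correlations through a fitted
  polynomial; those coefficients are not reproduced here and the trait
  correlation matrix is used directly. This is a mild approximation of the
  comparator (it understates m_e slightly for weakly correlated traits)
  and is acceptable because the comparators provide relative-power
  context, not primary results.
* MANOVA uses Wilks' Λ = det(E)/det(E + H) from the multivariate
  regression of the traits on intercept + genotype, with the exact
  one-predictor F transform F = (1−Λ)/Λ·(n−K−1)/K on (K, n−K−1) degrees
  of freedom. With a single predictor all four classical MANOVA statistics
  give identical p-values, so the choice among them is immaterial.

## Synthetic data

Traits are generated from the factor model

    y = lambda·x + c·gamma·f + sqrt(1 − c²)·eps,

with x drawn i.i.d. under Hardy–Weinberg equilibrium at minor-allele
frequency `maf`, f ~ MVN(0, Σ), Σ = (1−rho)I + rho·11ᵀ over R latent
factors, gamma assigning each trait to one factor with unit loading, and
eps i.i.d. standard normal. Every trait has unit marginal variance under
the null, so `beta` is directly an effect size in phenotypic SD units per
minor allele. Five loading layouts cover dense-to-sparse pleiotropy: all
traits affected through one factor (1); one factor block of five affected
(2); one of two (3); a single affected trait among five factor blocks (4)
or one factor (5). Affected traits occupy the trailing positions.

Defaults: maf = 0.3, rho = 0.2, K = 20, n = 1000. The loading constant c
has no canonical value; the default c = 0.5 gives within-factor trait
correlations of 0.25 — moderate for clinically related quantitative
traits. Null calibration is insensitive to c (the permutation test
conditions on the trait covariance), while power levels and even some
power *orderings* are not: in particular, the relative standing of TATES
under the dense model 1 improves with c, and MHT/MANOVA lose power in
model 1 as c grows (their noncentrality scales as K/(c²K + 1 − c²)).
Power checks in the test suite therefore assert orderings at mid-range
effect sizes rather than absolute levels, and one classical ordering
claim — TATES weakest when all traits are affected — holds only in the
near-uncorrelated regime c ≲ 0.2 and is not reproduced at the default;
the corresponding test documents this by failing honestly rather than by
moving c.

What the generator does not emulate: linkage disequilibrium (a single
variant is simulated), non-normal or heteroscedastic trait distributions,
relatedness and population structure, missing data, and covariate
effects. Passing tests therefore certify the algebra and calibration of
the tests under a clean factor model, not robustness to real-cohort
pathologies; the covariate-residualisation helper (regress traits and
genotype on principal components, test the residuals) is provided and
tested on a synthetic confounding scenario only.

Default effect-size grids for the power runner were fixed per model so
that power spans roughly 0.1–0.9 at n = 1000, K = 20, c = 0.5
(model 1: 0.03–0.12; model 2: 0.05–0.16; model 3: 0.04–0.13; models 4–5:
0.10–0.22); the grids are echoed in every report.

## Experiment scales and numerical choices

The reference design for type-I error uses 10,000 replicates with
B = 1000 permutations. The packaged checks run scaled versions — 500
replicates in the test suite, 2000 in `scripts/acceptance.py` — always at
the reference B = 1000 except where a quick B = 200 check at
alpha = 0.05 suffices, and always comparing against the binomial CI
alpha ± 1.96·sqrt(alpha(1−alpha)/R) computed for the replicate count
actually used. Power orderings use 150 replicates at B = 200 and
alpha = 0.05, with MHT/MANOVA compared paired on the same replicates.

Degenerate inputs: constant (or numerically constant) genotype vectors
raise a dedicated error; zero-variance traits are named in the error;
sample alignment is by ID intersection in phenotype order, and mismatched
IDs raise rather than silently matching by position. Genotypes may be
real-valued dosages; nothing requires integrality.

## Known limitations

* Single variant, quantitative traits, unrelated individuals only — no
  region-based, binary-trait, or mixed-model extensions.
* MHT and MHT-O p-values are permutation-only (resolution 1/B); very
  small significance levels require B beyond desk scale.
* The TATES comparator approximates p-value correlations by trait
  correlations (see above).
* The maximising weight vector is used only as a test statistic; no
  confidence intervals for the implied heritability are provided.
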