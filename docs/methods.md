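# Methods

## Scope and data model

The package fits whole-genome regressions to biallelic SNP dosages (0/1/2
copies of a designated allele) on a multi-breed dog population and evaluates
genomic prediction by repeated 5-fold cross-validation. Genotypes live in a
`GenotypeMatrix` (dosage matrix plus marker map and per-dog breed/sex
labels), one trait at a time in a `PhenotypeVector` (continuous or 0/1
binary; missing observations masked). Dogs with a missing value for the
analysis trait are excluded from that trait's fit and cross-validation but
remain in the genotype object and in the genomic relationship matrix.

Trait coding for the hip phenotype follows clinical convention: the per-dog
value is the mean Norberg angle over both hips (missing if either side is
missing), the low tail is truncated at 75 degrees to tame skew, and the
binary "case" label used for AUC is angle < 105 degrees — lower angles mean
worse hip conformation, so cross-validated prediction scores are negated
before AUC so that a higher score always means more case-like. Binary traits
are modelled with the same Gaussian likelihood on the 0/1 coding; no
threshold/probit link is implemented. For ranking-based evaluation (AUC)
the Gaussian fit is rank-equivalent to a liability model's posterior mean
to good approximation, which is the use case here.

## Genomic relationship matrix

VanRaden method 1 with observed allele frequencies:
`K = W W' / (2 sum_j p_j (1 - p_j))`, where column j of W is the dosage
column centered by `2 p_j`. Monomorphic markers are excluded from both W and
the denominator (their centered column is identically zero, so this changes
nothing except keeping the scaling honest). The eigendecomposition of K is
computed once and cached; both GBLUP fitting paths work in that basis.
Columns of W sum to zero exactly, and eigenvalues are clipped at zero after
verifying none is materially negative.

## GBLUP

Model: `y = mu + X beta + g + e`, `g ~ N(0, K sigma_g2)`,
`e ~ N(0, I sigma_e2)`, with an intercept plus treatment-coded breed and sex
dummies (alphabetically first level as reference; a single-level factor
contributes no column). A condition-number guard (cond > 1e10) raises on
confounded designs, naming the candidate columns.

**Exact path.** At fixed variance components the solution is generalized
least squares in the eigenbasis: with `K = U D U'`,
`v = sigma_g2 d + sigma_e2`, beta solves the GLS normal equations and
`g = sigma_g2 U (d / v) U'(y - X beta)`. This satisfies Henderson's
mixed-model equations; the residual check uses the K-multiplied form
`K (y - X beta - g) = (sigma_e2 / sigma_g2) g`, valid for singular K. When
variance components are not supplied, the restricted likelihood profiled to
the heritability `h2 = sigma_g2 / (sigma_g2 + sigma_e2)` is maximized by
bounded scalar search (`xatol = 1e-8`) on `h2 in [1e-6, 1 - 1e-6]`; the
phenotypic scale is then profiled out analytically. This REML path is
deterministic and serves as the oracle for the sampler.

**Gibbs path.** The sampler works on the rotated model
`U'y = U'X beta + a + U'e` with independent priors `a_i ~ N(0, sigma_g2 d_i)`
on the components with `d_i > 1e-10 max(d)`; components in the null space of
K contribute to the residual only. Full conditionals: beta is Gaussian (flat
prior), all `a_i` are conditionally independent Gaussians, and both variances
are scaled-inverse-chi-square. Variance priors have 5 degrees of freedom;
their scales are centered so the prior modes split the phenotypic variance
according to a *preliminary REML estimate* of h2 (empirical-Bayes centering,
clipped to [0.05, 0.95]). A fixed 50/50 split — the common shipped default —
pulls the posterior toward h2 = 0.5 noticeably at n = 500 (about -0.13 at
true h2 = 0.8), enough to distort heritability recovery; centering at the
REML value removes that pull while leaving the prior weight (df 5) intact.
Pass `prior_r2=0.5` for a data-independent prior. Reported h2 is the
posterior mean of `sigma_g2 / (sigma_g2 + sigma_e2)`.

**Prediction.** Held-out dogs get the conditional expectation
`g_new = K[new, train] (K[train, train] + ridge I)^-1 g_train` with ridge
`1e-6 tr(K)/n` for numerical stability, plus their fixed effects encoded
with the training levels (an unseen breed or sex level raises). Training
dogs get their fitted genetic values exactly. Allele-coding flips
(`x -> 2 - x`) leave K, and therefore all GBLUP predictions, unchanged.

## BayesC

Model: `y = mu + X beta + W alpha + e` on training-mean-centered marker
columns, with `alpha_j` a point mass at zero with probability `1 - pi` and
`N(0, sigma_a2)` with probability `pi`. A systematic-scan single-site Gibbs
sampler updates each `(delta_j, alpha_j)` pair from the standard marginal
Bayes factor `0.5 log(lambda / v) + r_j^2 / (2 sigma_e2 v)` with
`lambda = sigma_e2 / sigma_a2`, `v = w_j'w_j + lambda`; fixed effects are
sampled jointly (flat prior). Hyperparameters mirror the BGLR-style
defaults and are all configurable: prior inclusion probability 0.5 with
Beta prior weight 10; scaled-inverse-chi-square priors with df 5 for both
variances, scales chosen so the prior partitions the phenotypic variance
evenly (R2 = 0.5), with the marker-variance scale additionally divided by
the mean marker sum of squares and the prior inclusion probability.
Monomorphic training markers keep effect zero throughout. `pi` and either
variance can be fixed; `pi = 1` with fixed variances reduces the model to
Bayesian ridge regression, which is the closed-form check used in the tests,
and with `sigma_a2 = sigma_g2 / c` (c the VanRaden denominator) the model is
exactly classical GBLUP reparameterized (SNP-BLUP), verified at r > 0.99 on
genetic values.

Chain defaults are 12,000 iterations, 2,000 burn-in, thinning 5 — longer
than typical shipped defaults, which are too short for stable posterior
means. One root seed per fit drives a single `numpy` Generator; identical
seeds give bitwise-identical chains.

## Cross-validation designs

Three sampling strategies over 5 folds (fold sizes differ by at most one;
shuffle then block-split, remainders one per fold):

* `random` — the whole population is partitioned each round;
* `single_breed` — only the target breed is partitioned; all other dogs are
  excluded;
* `single_breed_augmented` — identical folds on the target breed (the two
  strategies consume randomness identically, so validation sets coincide
  for a given seed), but every other-breed dog stays permanently in the
  reference panel.

For each round x fold the model is fitted on the reference dogs and the
validation dogs are predicted; GBLUP uses the joint GRM computed once over
all dogs (no phenotype leakage — only genotypes are shared). Fold metrics
are Pearson r and, when binary labels exist, AUC. Folds with fewer than 3
validation dogs, a constant training trait, a constant prediction, or a
single label class are skipped with a logged warning and counted. Fold
metrics are averaged within round first; the reported mean and SD are
across rounds. The default GBLUP fitting path inside CV is closed-form REML
(deterministic and fast enough for 100 rounds); `method="gibbs"` and
`model="bayesc"` run the samplers with per-fold seeds derived from the plan
seed via `SeedSequence`.

## Synthetic data generator

The generator emulates a six-breed SNP-array study. Each marker draws an
ancestral frequency `p ~ U(0.05, 0.95)`; each breed draws its own frequency
from the Balding-Nichols distribution
`Beta(p (1-F)/F, (1-p)(1-F)/F)` with breed divergence F (default FST 0.15,
within the range reported between dog breeds); dosages are binomial(2, p).
Default breed sizes are the study census 398/137/97/80/68/62 halved
(199/68/49/40/34/31, 421 dogs) for desk-speed runs. Markers are spread over
the 38 dog autosomes with increasing positions.

Traits are additive with 20 causal markers (QTNs) drawn uniformly from the
polymorphic markers, *shared across breeds*, with standard-normal effects.
Each breed's residual variance is `var_g,breed (1 - h2) / h2` so realized
per-breed heritability matches its target (drawn `U(0.2, 0.8)` by default,
or fixed/per-breed mappings); `h2 = 1` means zero residual and `h2 = 0`
means pure noise with no genetic contribution. Binary traits threshold the
continuous liability at its empirical `(1 - prevalence)` quantile. Optional
breed intercepts and a sex effect can be added. A truth record (QTN ids,
effects, genetic values, realized heritabilities) accompanies every
simulated trait for recovery testing.

`write_fixture_bundle` emits a complete 300-dog miniature study —
PLINK triple, phenotype TSV with left/right hip angles (whose mean is the
simulated trait on a 100 +/- 8 degree scale), an RCCL-like binary trait at
44% prevalence, a weight-like control trait, gene intervals that each cover
a true QTN, and the truth JSON — byte-identical for a given seed.

**What the generator does not emulate.** Markers are in linkage
equilibrium: there is no within-chromosome LD, no pedigree or family
structure, and no selection. Consequently the causal variants are always
directly observed with identical effects in every breed, and information
transfers across breeds far more readily than in real dog data, where
breed-specific LD phase limits transfer. Tests passing on this generator
validate the estimators and the cross-validation machinery, not claims
about real across-breed prediction. Concretely: random multi-breed CV
beats pure single-breed CV here (as in the motivating study), but
augmenting a single-breed reference with other breeds *improves* accuracy
by ~0.08-0.09 in mean r under this generator, whereas on real dogs such
augmentation changes little — the one behavioral contrast this generator
cannot reproduce, and the reason the corresponding check in
`tests/test_acceptance.py` is expected to fail.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down sizes chosen as standard
desk-scale study conditions: 20 random instances at n <= 50, L <= 100 for
the solver oracle; n = 500, L = 2000 with 10 replicates per level for
heritability recovery; n = 500, L = 500 with 10 CV rounds for the accuracy
bounds; and 10 replicate six-breed populations (421 dogs, L = 1000, 10
rounds) for the sampling-strategy contrast. Eigenvalues below `1e-10 max(d)`
are treated as null-space; the GRM denominator guards against zero; the
REML search is bounded away from 0 and 1; predictions through the kinship
use a `1e-6 tr(K)/n` ridge. The 105-degree binarization assigns the
boundary value to the control class; the 75-degree floor is inclusive.

## Known limitations

* Gaussian treatment of binary traits (no probit/threshold model).
* No LD, pedigree, or selection in the generator (above).
* Heritability estimates from a 20-QTN architecture at n = 500 carry large
  sampling noise (single-replicate REML/posterior h2 can be off by ~0.15);
  recovery statements hold for means over replicates.
* Single-step (pedigree-blended) BLUP, BayesA/B/Bayesian-LASSO variants,
  GWAS p-values, imputation, and phasing are out of scope.
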